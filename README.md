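# chelcomp

Competitive-chelator NMR titration analysis: determine a protein's metal
(Zn²⁺) dissociation constant by letting it compete with a chelator of known
affinity (e.g. NTA, Kd = 4.4 nM) for a shared metal pool, quantified from
2D HSQC peak intensities and 1D reference/chelator signal ratios.

## What it does

- **`chelcomp.equilibrium`** — mass-action solver for the three-component
  protein/chelator/Zn system (monotone scalar metal balance, bracketed root
  finding), free-fraction titration curves, an independent bisection oracle
  and a two-protein competition extension.
- **`chelcomp.intensity`** — peak selection (distinct-peak flag + SNR > 4 at
  every titration point), apo-protein quantification from intensity ratios
  (mean ± std over peaks), sedimentation drift estimation from a zero-Zn time
  series with optional detrending, and 1D chelator-bound quantification from
  the buffer-reference ratio.
- **`chelcomp.inference`** — per-point Kd inversion (preferring the 1D
  chelator channel to pin the metal partition when available), error-weighted
  averaging, a joint weighted least-squares fit in log-Kd, a stoichiometry
  slope diagnostic and a restricted-degrees-of-freedom pooled t-test for
  comparing constants (df = n₁ + n₂ − restriction).
- **`chelcomp.interaction`** — protein-protein interaction screen:
  reference-peak normalization, zero-intercept slope + Pearson correlation of
  spectra, and per-point apo-trajectory competition tests
  (peaks-as-replicates, df = n₁ + n₂ − 2).
- **`chelcomp.synthetic`** — seeded generators for competitive titrations and
  two-protein mixtures with multiplicative lognormal peak noise, per-peak
  intensity heterogeneity and linear sedimentation drift, plus ground-truth
  sidecars.
- **`chelcomp.pipeline` / `chelcomp.cli`** — end-to-end analysis and the
  `chelcomp` command-line tool.

Units: concentrations in files and CLI options are μM, dissociation constants
in reports are nM; the equilibrium core works in molar.

## CLI

```sh
# generate a synthetic competitive titration (config is YAML; seed mandatory)
cat > wt.yaml <<EOF
kd_p_true: 6.0     # ground-truth Kd, nM
seed: 20250303
p_total: 200.0     # uM
c_total: 200.0     # uM chelator
EOF
chelcomp simulate --config wt.yaml --out-dir data/wt

# fit the dissociation constant (per-point inversion by default)
chelcomp fit --peaks data/wt/peaks.csv --chelator data/wt/chelator.csv \
    --p-total 200 --c-total 200 --out wt_report.json

# compare two fitted constants (restricted-df t-test, df = n1+n2-3)
chelcomp compare wt_report.json mutant_report.json --out cmp.json

# interaction screen between two peak tables
chelcomp interaction --with-partner mix.csv --without-partner alone.csv \
    --reference-peak peak1 --out interaction.json
```

Exit codes: 0 success, 1 validation error, 2 runtime error.

Peak tables are CSV with columns
`peak_id, point_index, zn_added, time_h, intensity, noise, distinct`;
1D chelator tables have `point_index, i_ref, i_chel`.

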