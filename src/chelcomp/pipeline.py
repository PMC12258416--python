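"""End-to-end analysis helpers tying the stages together.

These are the same steps the CLI runs: peak selection, apo quantification
(with optional drift detrending), 1D chelator quantification and Kd fitting.
The replicate-recovery driver used by the acceptance experiments also lives
here so that scripted runs and tests share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chelcomp.errors import ValidationError
from chelcomp.inference import KdEstimate, fit_kd, stoichiometry_slope
from chelcomp.intensity import (
    ApoSeries,
    PeakTable,
    apo_concentration,
    chelator_bound,
    sedimentation_correction,
    select_peaks,
)
from chelcomp.synthetic import (
    SyntheticConfig,
    simulate_drift_series,
    simulate_titration,
)


@dataclass(frozen=True)
class TitrationAnalysis:
    estimate: KdEstimate
    series: ApoSeries
    peaks: tuple[str, ...]
    slope: float | None
    czn: dict[int, float] | None


def chelator_bound_by_point(
    chelator: pd.DataFrame,
    zn_by_point: dict[int, float],
    c_total: float,
    mode: str,
    ref_conc: float | None = None,
    calib: float = 1.0,
) -> dict[int, float]:
    """Per-point chelator-bound Zn (μM) from a 1D table.

    The chelator total at each point follows the protocol: constant in
    ``zn_only`` mode, ``c_total + zn`` in premixed mode.
    """
    kwargs = {} if ref_conc is None else {"ref_conc": ref_conc}
    out: dict[int, float] = {}
    for _, row in pd.DataFrame(chelator).iterrows():
        pi = int(row["point_index"])
        zn = zn_by_point.get(pi)
        if zn is None:
            continue
        ct = c_total if mode == "zn_only" else c_total + zn
        if ct <= 0:
            continue
        one = chelator_bound(row.to_frame().T, c_total=ct, calib=calib, **kwargs)
        out[pi] = float(one["bound"].iloc[0])
    return out


def analyze_titration(
    table: PeakTable,
    chelator: pd.DataFrame | None = None,
    *,
    p_total: float,
    c_total: float,
    kd_c: float = 4.4,
    mode: str = "zn_only",
    method: str = "per_point",
    snr_min: float = 4.0,
    drift_per_h: float | None = None,
    ref_conc: float | None = None,
    calib: float = 1.0,
) -> TitrationAnalysis:
    """Full single-experiment analysis: peaks -> apo series -> Kd estimate."""
    peaks = select_peaks(table, snr_min=snr_min)
    series = apo_concentration(table, peaks, drift_per_h=drift_per_h)
    czn = None
    if chelator is not None:
        zn_by_point = dict(
            zip(series.data["point_index"].astype(int), series.zn_added)
        )
        czn = chelator_bound_by_point(
            chelator, zn_by_point, c_total, mode, ref_conc=ref_conc, calib=calib
        )
        if not czn:
            czn = None
    estimate = fit_kd(
        series, p_total=p_total, c_total=c_total, kd_c=kd_c, mode=mode, method=method, czn=czn
    )
    try:
        slope = stoichiometry_slope(series, p_total)
    except ValidationError:
        slope = None
    return TitrationAnalysis(
        estimate=estimate, series=series, peaks=tuple(peaks), slope=slope, czn=czn
    )


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds spawned from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def recover_kd_replicates(
    kd_true: float,
    n_replicates: int,
    master_seed: int,
    protocol: str = "zn_only",
    method: str = "per_point",
    use_chelator_1d: bool = True,
    detrend: bool = True,
    **config_overrides,
) -> np.ndarray:
    """Recovered Kd (nM) over seeded synthetic replicates.

    Each replicate simulates a full competitive titration with ``kd_true``
    (nM) as ground truth, estimates the sedimentation drift from its own
    zero-Zn calibration series, and runs :func:`analyze_titration`.
    Failed replicates yield NaN.
    """
    results = np.full(n_replicates, np.nan)
    for k, seed in enumerate(replicate_seeds(master_seed, n_replicates)):
        cfg = SyntheticConfig(
            kd_p_true=kd_true, seed=seed, protocol=protocol, **config_overrides
        )
        table, chelator, _ = simulate_titration(cfg)
        drift = None
        if detrend:
            drift, _ = sedimentation_correction(simulate_drift_series(cfg))
        c_total = cfg.c_total if cfg.protocol == "zn_only" else cfg.premix_base
        try:
            analysis = analyze_titration(
                table,
                chelator if use_chelator_1d else None,
                p_total=cfg.p_total,
                c_total=c_total,
                kd_c=cfg.kd_c,
                mode=cfg.protocol,
                method=method,
                drift_per_h=drift,
                ref_conc=cfg.ref_conc,
                calib=cfg.calib,
            )
        except Exception:
            continue
        results[k] = analysis.estimate.kd
    return results
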