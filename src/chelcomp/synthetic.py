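"""Seeded generators for synthetic titration and mixture datasets.

The generators emit the same table dialects the analysis consumes, together
with a ground-truth sidecar, so every pipeline stage is testable without any
experimental download.  Noise is multiplicative lognormal (unit mean,
coefficient of variation ``noise_cv``); sedimentation is a linear intensity
decay in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from chelcomp.equilibrium import (
    CompetitionSystem,
    solve_competition,
    solve_two_proteins,
)
from chelcomp.errors import ValidationError
from chelcomp.intensity import DEFAULT_REF_CONC, PeakTable

UM = 1e-6
NM = 1e-9

DEFAULT_ZN_POINTS = (0.0, 12.5, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0)

#: Arbitrary-unit intensity of a fully free protein peak and the spectral
#: noise floor (SNR 50 at the control point).
BASE_INTENSITY = 100.0
NOISE_FLOOR = 2.0

#: 1D reference (buffer) signal intensity, arbitrary units.
REF_INTENSITY_1D = 1000.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of a simulated competitive titration.

    Kd values in nM, concentrations in μM.  In ``premixed_chelator_zn`` mode
    the chelator is added 1:1 with Zn on top of ``premix_base`` and
    ``c_total`` is ignored.
    """

    kd_p_true: float
    seed: int
    kd_c: float = 4.4
    p_total: float = 200.0
    c_total: float = 200.0
    premix_base: float = 0.0
    protocol: str = "zn_only"
    zn_points: tuple[float, ...] = DEFAULT_ZN_POINTS
    n_peaks: int = 6
    noise_cv: float = 0.05
    drift_per_h: float = 0.005
    hours_per_point: float = 1.0
    irreversible_fraction: float = 0.0
    ref_conc: float = DEFAULT_REF_CONC
    calib: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None or int(self.seed) != self.seed:
            raise ValidationError("an integer seed is mandatory")
        if not self.kd_p_true > 0 or not self.kd_c > 0:
            raise ValidationError("dissociation constants must be > 0")
        for name in ("p_total", "c_total", "premix_base", "drift_per_h",
                     "hours_per_point", "irreversible_fraction"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.noise_cv < 1.0:
            raise ValidationError("noise_cv must lie in [0, 1)")
        if self.n_peaks < 1:
            raise ValidationError("n_peaks must be >= 1")
        if self.protocol not in ("zn_only", "premixed_chelator_zn"):
            raise ValidationError(f"unknown protocol {self.protocol!r}")
        pts = tuple(float(z) for z in self.zn_points)
        if not pts or pts[0] != 0.0 or any(b <= a for a, b in zip(pts, pts[1:])):
            raise ValidationError("zn_points must start at 0 and increase strictly")
        object.__setattr__(self, "zn_points", pts)

    def chelator_totals(self) -> tuple[float, ...]:
        if self.protocol == "zn_only":
            return tuple(self.c_total for _ in self.zn_points)
        return tuple(self.premix_base + z for z in self.zn_points)


@dataclass(frozen=True)
class SyntheticTruth:
    """Noise-free quantities underlying a generated dataset."""

    config: SyntheticConfig
    free_fractions: tuple[float, ...]
    czn: tuple[float, ...] = ()
    c_totals: tuple[float, ...] = ()


#: Dispersion (lognormal sigma) of per-peak base intensities.
_PEAK_SCALE_SIGMA = 0.4


def _peak_scales(cfg: SyntheticConfig) -> np.ndarray:
    """Per-peak base intensity scales, deterministic per config seed.

    Keyed only by ``cfg.seed`` so the same protein keeps the same spectrum
    across datasets (e.g. with/without a binding partner), as real peak
    heights would.
    """
    rng = np.random.default_rng([int(cfg.seed), 0xBA5E])
    return rng.lognormal(mean=0.0, sigma=_PEAK_SCALE_SIGMA, size=cfg.n_peaks)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _solve_point(cfg: SyntheticConfig, zn: float, c_tot: float) -> tuple[float, float]:
    system = CompetitionSystem(
        cfg.p_total * UM, c_tot * UM, zn * UM, cfg.kd_p_true * NM, cfg.kd_c * NM
    )
    state = solve_competition(system)
    return state.p_free / system.p_total, state.czn / UM


def simulate_titration(
    cfg: SyntheticConfig,
) -> tuple[PeakTable, pd.DataFrame, SyntheticTruth]:
    """Generate one competitive titration: 2D peak table, 1D chelator table
    and the generating truth.

    Per point, the true free fraction comes from the forward equilibrium
    solve; each peak intensity is
    ``BASE * fraction * (1 - drift*t) * (1 - irrev*(1 - fraction)) * noise``.
    The 1D chelator intensities encode the true bound-chelator concentration
    through the same ratio formula the reader inverts.
    """
    rng = np.random.default_rng(cfg.seed)
    scales = _peak_scales(cfg)
    c_totals = cfg.chelator_totals()
    fractions: list[float] = []
    czn_true: list[float] = []
    rows = []
    chel_rows = []
    for i, (zn, c_tot) in enumerate(zip(cfg.zn_points, c_totals)):
        frac, czn = _solve_point(cfg, zn, c_tot)
        fractions.append(frac)
        czn_true.append(czn)
        t = i * cfg.hours_per_point
        decay = (1.0 - cfg.drift_per_h * t) * (1.0 - cfg.irreversible_fraction * (1.0 - frac))
        if decay < 0:
            raise ValidationError("drift/irreversible loss exceeds total signal")
        noise = _lognormal_factors(rng, cfg.noise_cv, cfg.n_peaks)
        for j in range(cfg.n_peaks):
            rows.append(
                {
                    "peak_id": f"peak{j + 1}",
                    "point_index": i,
                    "zn_added": zn,
                    "time_h": t,
                    "intensity": BASE_INTENSITY * scales[j] * frac * decay * noise[j],
                    "noise": NOISE_FLOOR,
                    "distinct": True,
                }
            )
        chel_rows.append(
            {
                "point_index": i,
                "i_ref": REF_INTENSITY_1D,
                "i_chel": czn * REF_INTENSITY_1D / (cfg.ref_conc * cfg.calib),
            }
        )
    table = PeakTable(pd.DataFrame(rows), control_conc=cfg.p_total, control_point=0)
    chelator = pd.DataFrame(chel_rows)
    truth = SyntheticTruth(
        config=cfg,
        free_fractions=tuple(fractions),
        czn=tuple(czn_true),
        c_totals=tuple(c_totals),
    )
    return table, chelator, truth


def simulate_drift_series(
    cfg: SyntheticConfig, n_times: int = 8
) -> PeakTable:
    """Zero-Zn time series for calibrating the sedimentation correction.

    Uses a seed stream distinct from (but derived from) ``cfg.seed`` so the
    calibration noise is independent of the titration noise.
    """
    if n_times < 2:
        raise ValidationError("need >= 2 time points")
    rng = np.random.default_rng([int(cfg.seed), 0xD81F7])
    scales = _peak_scales(cfg)
    rows = []
    for i in range(n_times):
        t = i * cfg.hours_per_point
        noise = _lognormal_factors(rng, cfg.noise_cv, cfg.n_peaks)
        for j in range(cfg.n_peaks):
            rows.append(
                {
                    "peak_id": f"peak{j + 1}",
                    "point_index": i,
                    "zn_added": 0.0,
                    "time_h": t,
                    "intensity": BASE_INTENSITY
                    * scales[j]
                    * (1.0 - cfg.drift_per_h * t)
                    * noise[j],
                    "noise": NOISE_FLOOR,
                    "distinct": True,
                }
            )
    return PeakTable(pd.DataFrame(rows), control_conc=cfg.p_total, control_point=0)


def simulate_mixture(
    cfg_a: SyntheticConfig,
    cfg_b: SyntheticConfig,
    zn_points: tuple[float, ...] | None = None,
    seed: int | None = None,
) -> tuple[PeakTable, PeakTable, dict]:
    """Two proteins sharing one Zn pool (no chelator): per-protein tables.

    Each protein's peak intensities depend only on its own free fraction
    (the no-interaction null); noise streams are independent.  Returns the
    two peak tables and a truth dict with both free-fraction curves.
    """
    pts = tuple(float(z) for z in (zn_points or cfg_a.zn_points))
    if not pts or pts[0] != 0.0 or any(b <= a for a, b in zip(pts, pts[1:])):
        raise ValidationError("zn_points must start at 0 and increase strictly")
    seed = cfg_a.seed if seed is None else seed
    frac_a: list[float] = []
    frac_b: list[float] = []
    for zn in pts:
        _, fa, fb = solve_two_proteins(
            cfg_a.p_total * UM,
            cfg_a.kd_p_true * NM,
            cfg_b.p_total * UM,
            cfg_b.kd_p_true * NM,
            zn * UM,
        )
        frac_a.append(fa)
        frac_b.append(fb)
    rng = np.random.default_rng(seed)
    table_a = _mixture_table(cfg_a, pts, frac_a, rng)
    table_b = _mixture_table(cfg_b, pts, frac_b, rng)
    truth = {
        "zn_points": list(pts),
        "free_fractions_a": frac_a,
        "free_fractions_b": frac_b,
    }
    return table_a, table_b, truth


def _mixture_table(
    cfg: SyntheticConfig,
    zn_points: tuple[float, ...],
    fractions: list[float],
    rng: np.random.Generator,
) -> PeakTable:
    scales = _peak_scales(cfg)
    rows = []
    for i, (zn, frac) in enumerate(zip(zn_points, fractions)):
        t = i * cfg.hours_per_point
        noise = _lognormal_factors(rng, cfg.noise_cv, cfg.n_peaks)
        for j in range(cfg.n_peaks):
            rows.append(
                {
                    "peak_id": f"peak{j + 1}",
                    "point_index": i,
                    "zn_added": zn,
                    "time_h": t,
                    "intensity": BASE_INTENSITY
                    * scales[j]
                    * frac
                    * (1.0 - cfg.drift_per_h * t)
                    * noise[j],
                    "noise": NOISE_FLOOR,
                    "distinct": True,
                }
            )
    return PeakTable(pd.DataFrame(rows), control_conc=cfg.p_total, control_point=0)


def wt_like_config(kd_p_true: float = 6.0, seed: int = 20250303, **overrides) -> SyntheticConfig:
    """Default experiment configuration (200 μM protein and chelator,
    Zn 0-200 μM, 6 peaks, 5% noise) with a chosen ground-truth Kd."""
    return replace(SyntheticConfig(kd_p_true=kd_p_true, seed=seed), **overrides)
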