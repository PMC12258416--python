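"""Dissociation-constant estimation from apo-protein titration series and
restricted-degrees-of-freedom comparison of fitted constants.

Interfaces use the reporting units of the domain: concentrations in μM,
dissociation constants in nM.  Internally everything is converted to molar
before touching the equilibrium model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from chelcomp.equilibrium import CompetitionSystem, solve_competition
from chelcomp.errors import FitError, NonInformativePointWarning, ValidationError
from chelcomp.intensity import ApoSeries

UM = 1e-6
NM = 1e-9

#: log10(Kd/M) search window for the global fit.
_LOG_KD_BOUNDS = (-12.0, -2.0)

#: Significance thresholds and their star labels, most stringent first.
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for level, label in STAR_LEVELS:
        if p < level:
            return label
    return "ns"


@dataclass(frozen=True)
class KdEstimate:
    """Fitted dissociation constant (nM) with uncertainty and sample size."""

    kd: float
    sd: float
    n_points: int
    method: str
    per_point_values: tuple[float, ...] = ()
    per_point_errors: tuple[float, ...] = ()
    excluded: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValidationError(f"kd must be > 0, got {self.kd}")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n_points < 1:
            raise ValidationError("n_points must be >= 1")


@dataclass(frozen=True)
class TTestResult:
    """Two-sample comparison with a restricted degrees-of-freedom count."""

    t: float
    df: int
    p: float
    restriction: int
    stars: str = field(default="")

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValidationError("df must be >= 1")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError("p must lie in [0, 1]")
        if not self.stars:
            object.__setattr__(self, "stars", significance_stars(self.p))


def _positive_quadratic_root(b: float, c: float) -> float:
    """Larger root of z^2 + b z + c = 0 with c <= 0, numerically stable."""
    disc = math.sqrt(b * b - 4.0 * c)
    if b > 0:
        return -2.0 * c / (b + disc) if disc + b != 0 else 0.0
    return 0.5 * (-b + disc)


def _zn_free_from_balance(zn_avail: float, c_total: float, kd_c: float) -> float:
    """Free Zn given Zn not bound to protein, from the chelator isotherm.

    Solves z + c_total*z/(kd_c+z) = zn_avail (all molar).
    """
    b = kd_c + c_total - zn_avail
    c = -kd_c * zn_avail
    return _positive_quadratic_root(b, c)


def kd_from_point(
    apo: float,
    p_total: float,
    zn_total: float,
    c_total: float,
    kd_c: float = 4.4,
    czn_measured: float | None = None,
) -> float:
    """Single-point Kd inversion (result in nM).

    ``apo``, ``p_total``, ``zn_total``, ``c_total`` and ``czn_measured`` are
    in μM; ``kd_c`` in nM.

    With a measured chelator-bound concentration the chelator side fully
    determines the metal partition: free chelator is ``c_total - czn``, free
    Zn follows from the chelator isotherm and protein-bound Zn from the
    metal balance, so the (noisier) protein intensity only enters linearly
    through ``apo``.  Without 1D data, protein-bound Zn is ``p_total - apo``
    and free Zn comes from the chelator mass balance with known ``kd_c``.
    Raises :class:`ValidationError` when the point is non-informative.
    """
    apo_m, p_m, zn_m, c_m = apo * UM, p_total * UM, zn_total * UM, c_total * UM
    kd_c_m = kd_c * NM
    if not 0.0 < apo_m:
        raise ValidationError("apo must be > 0")
    if czn_measured is not None:
        czn_m = czn_measured * UM
        c_free = c_m - czn_m
        if c_free <= 0.0:
            raise ValidationError("chelator fully bound: free Zn indeterminate")
        zn_free = kd_c_m * czn_m / c_free
        pzn = zn_m - czn_m - zn_free
        if zn_free <= 0.0 or pzn <= 0.0:
            raise ValidationError("metal balance leaves no protein-bound Zn at this point")
    else:
        if apo_m >= p_m:
            raise ValidationError("apo >= p_total: no detectable binding at this point")
        pzn = p_m - apo_m
        zn_avail = zn_m - pzn
        if zn_avail <= 0.0:
            raise ValidationError("protein-bound Zn exceeds total Zn at this point")
        zn_free = _zn_free_from_balance(zn_avail, c_m, kd_c_m)
        if zn_free <= 0.0:
            raise ValidationError("free Zn <= 0 from the chelator balance")
    return (apo_m * zn_free / pzn) / NM


def _model_apo(kd_m: float, p_m: float, c_m: float, zn_m: float, kd_c_m: float) -> float:
    state = solve_competition(CompetitionSystem(p_m, c_m, zn_m, kd_m, kd_c_m))
    return state.p_free


def _per_point_c_totals(zn: np.ndarray, c_total: float, mode: str) -> np.ndarray:
    if mode == "zn_only":
        return np.full_like(zn, c_total)
    if mode == "premixed_chelator_zn":
        return c_total + zn
    raise ValidationError(f"unknown protocol mode {mode!r}")


def fit_kd(
    series: ApoSeries,
    p_total: float,
    c_total: float,
    kd_c: float = 4.4,
    mode: str = "zn_only",
    method: str = "per_point",
    czn: dict[int, float] | None = None,
) -> KdEstimate:
    """Estimate the protein:Zn Kd (nM) from an apo-concentration series.

    ``per_point`` inverts every informative titration point independently and
    reports the error-weighted mean (spread-based weighted sd); ``global``
    minimizes the error-weighted squared mismatch between the forward model
    and the measured apo concentrations over log-Kd.

    ``czn`` optionally maps point_index to measured chelator-bound Zn (μM);
    when present it is preferred over the model-based chelator balance in the
    per-point inversion.  Concentrations in μM, ``kd_c`` in nM; in premixed
    mode ``c_total`` is the pre-existing (base) chelator concentration.
    """
    if method not in ("per_point", "global"):
        raise ValidationError(f"method must be per_point or global, got {method!r}")
    df = series.data
    zn = df["zn_added"].to_numpy(float)
    apo = df["apo"].to_numpy(float)
    err = df["error"].to_numpy(float)
    points = df["point_index"].to_numpy(int)
    c_totals = _per_point_c_totals(zn, c_total, mode)
    informative = zn > 0.0
    if not informative.any():
        raise FitError("no titration point with added Zn: cannot estimate Kd")

    if method == "global":
        return _fit_global(zn, apo, err, c_totals, points, p_total, kd_c)

    values: list[float] = []
    errors: list[float] = []
    excluded: list[tuple[int, str]] = []
    for i in np.flatnonzero(informative):
        czn_i = czn.get(int(points[i])) if czn is not None else None
        try:
            kd_i = kd_from_point(apo[i], p_total, zn[i], c_totals[i], kd_c, czn_i)
        except ValidationError as exc:
            warnings.warn(
                f"point {points[i]} excluded: {exc}", NonInformativePointWarning, stacklevel=2
            )
            excluded.append((int(points[i]), str(exc)))
            continue
        values.append(kd_i)
        errors.append(_propagate_apo_error(apo[i], err[i], p_total, zn[i], c_totals[i], kd_c, czn_i))
    if not values:
        raise FitError(
            "no informative titration point: "
            + "; ".join(f"point {p}: {r}" for p, r in excluded)
        )
    kd_arr = np.asarray(values)
    sd_arr = np.asarray(errors)
    weights = _weights_from_errors(sd_arr)
    kd_hat = float(np.average(kd_arr, weights=weights))
    n = len(kd_arr)
    if n > 1:
        var = float(np.average((kd_arr - kd_hat) ** 2, weights=weights)) * n / (n - 1)
        sd_hat = math.sqrt(var)
    else:
        sd_hat = float(sd_arr[0])
    return KdEstimate(
        kd=kd_hat,
        sd=sd_hat,
        n_points=n,
        method="per_point",
        per_point_values=tuple(kd_arr),
        per_point_errors=tuple(sd_arr),
        excluded=tuple(excluded),
    )


def _weights_from_errors(sd: np.ndarray) -> np.ndarray:
    if np.all(sd == 0):
        return np.ones_like(sd)
    floor = sd[sd > 0].min()
    safe = np.where(sd > 0, sd, floor)
    return 1.0 / safe**2


def _propagate_apo_error(
    apo: float,
    err: float,
    p_total: float,
    zn_total: float,
    c_total: float,
    kd_c: float,
    czn_i: float | None,
) -> float:
    """Half-range finite-difference propagation of the apo error into Kd."""
    if err == 0:
        return 0.0
    lo = max(apo - err, 1e-9 * p_total)
    hi = apo + err
    if czn_i is None:
        hi = min(hi, p_total * (1 - 1e-12))
    vals = []
    for a in (lo, hi):
        try:
            vals.append(kd_from_point(a, p_total, zn_total, c_total, kd_c, czn_i))
        except ValidationError:
            continue
    if len(vals) < 2:
        kd_mid = kd_from_point(apo, p_total, zn_total, c_total, kd_c, czn_i)
        return abs(vals[0] - kd_mid) if vals else float("inf")
    return 0.5 * abs(vals[1] - vals[0])


def _fit_global(
    zn: np.ndarray,
    apo: np.ndarray,
    err: np.ndarray,
    c_totals: np.ndarray,
    points: np.ndarray,
    p_total: float,
    kd_c: float,
) -> KdEstimate:
    p_m = p_total * UM
    kd_c_m = kd_c * NM
    zn_m = zn * UM
    c_m = c_totals * UM
    apo_m = apo * UM
    if np.any(err > 0):
        floor = err[err > 0].min()
        w = 1.0 / (np.where(err > 0, err, floor) * UM) ** 2
        weighted = True
    else:
        w = np.ones_like(apo)
        weighted = False

    def chi2(log_kd: float) -> float:
        kd_m = 10.0**log_kd
        resid = np.array(
            [_model_apo(kd_m, p_m, c_m[i], zn_m[i], kd_c_m) - apo_m[i] for i in range(len(zn))]
        )
        return float(np.sum(w * resid**2))

    res = minimize_scalar(chi2, bounds=_LOG_KD_BOUNDS, method="bounded", options={"xatol": 1e-9})
    log_kd = float(res.x)
    kd_m = 10.0**log_kd
    # curvature-based uncertainty in log10(Kd), rescaled by the reduced chi2
    h = 1e-3
    c0, cp, cm_ = chi2(log_kd), chi2(log_kd + h), chi2(log_kd - h)
    curv = (cp + cm_ - 2.0 * c0) / h**2
    n_inf = int(np.sum(zn > 0))
    dof = max(n_inf - 1, 1)
    if curv > 0:
        var_log = 2.0 / curv
        if weighted:
            # inflate by the reduced chi2 so under/over-stated point errors
            # do not distort the reported uncertainty
            var_log *= max(c0 / dof, 1e-30)
        sd_m = kd_m * math.log(10.0) * math.sqrt(var_log)
    else:
        sd_m = kd_m  # flat objective: uncertainty of the order of the value
    return KdEstimate(
        kd=kd_m / NM,
        sd=sd_m / NM,
        n_points=n_inf,
        method="global",
    )


def compare_kds(a: KdEstimate, b: KdEstimate, restriction: int = 3) -> TTestResult:
    """Pooled-variance two-sample t-test on log-Kd with restricted df.

    The degrees of freedom are ``a.n_points + b.n_points - restriction``
    (the restriction counts the independent variables of the underlying
    equation system); the same denominator pools the variances, so
    ``restriction=2`` reduces to the classic textbook formula.
    """
    n1, n2 = a.n_points, b.n_points
    df = n1 + n2 - restriction
    if df < 1:
        raise ValidationError(f"degrees of freedom {df} < 1 (n1={n1}, n2={n2})")
    m1, m2 = math.log(a.kd), math.log(b.kd)
    s1, s2 = a.sd / a.kd, b.sd / b.kd  # delta-method log-scale sd
    pooled = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    denom = math.sqrt(pooled * (1.0 / n1 + 1.0 / n2)) if pooled > 0 else 0.0
    if denom == 0.0:
        t = 0.0 if m1 == m2 else math.inf * (1 if m1 > m2 else -1)
    else:
        t = (m1 - m2) / denom
    p = float(2.0 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return TTestResult(t=float(t), df=df, p=p, restriction=restriction)


def stoichiometry_slope(series: ApoSeries, p_total: float) -> float:
    """Slope of the bound fraction versus added Zn equivalents.

    Least-squares slope of ``1 - apo/p_total`` against ``zn/p_total`` over
    the sub-stoichiometric points (``zn <= p_total``); a value near 1 is the
    tight 1:1 binding diagnostic.
    """
    zn = series.zn_added
    mask = zn <= p_total
    if int(mask.sum()) < 2:
        raise ValidationError("need >= 2 points with zn_total <= p_total")
    x = zn[mask] / p_total
    y = 1.0 - series.apo[mask] / p_total
    return float(np.polyfit(x, y, 1)[0])
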