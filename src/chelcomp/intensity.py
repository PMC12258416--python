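"""Peak-intensity quantification: SNR selection, apo-concentration series,
sedimentation correction and 1D chelator quantification.

Concentration I/O in this module is in μM; peak intensities are in arbitrary
units and only their ratios matter (all estimators are scale invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chelcomp.errors import SelectionError, ValidationError

PEAK_COLUMNS = ["peak_id", "point_index", "zn_added", "time_h", "intensity", "noise", "distinct"]
CHELATOR_COLUMNS = ["point_index", "i_ref", "i_chel"]

#: Default internal-reference (buffer) concentration, μM (30 mM MOPS).
DEFAULT_REF_CONC = 30_000.0


@dataclass
class PeakTable:
    """Per-peak intensity measurements across titration points.

    ``data`` holds one row per (peak, titration point) with columns
    ``peak_id, point_index, zn_added, time_h, intensity, noise, distinct``.
    ``control_conc`` is the spectrophotometric protein concentration (μM)
    of the zero-Zn control point.
    """

    data: pd.DataFrame
    control_conc: float
    control_point: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in PEAK_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"peak table missing columns: {missing}")
        df = df[PEAK_COLUMNS]
        df["distinct"] = df["distinct"].astype(bool)
        for col in ("zn_added", "time_h", "intensity", "noise"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        if (df["intensity"] < 0).any():
            raise ValidationError("intensity must be >= 0")
        if (df["noise"] <= 0).any():
            raise ValidationError("noise must be > 0")
        if (df["time_h"] < 0).any():
            raise ValidationError("time_h must be >= 0")
        if not float(self.control_conc) > 0:
            raise ValidationError("control_conc must be > 0")
        self.control_conc = float(self.control_conc)
        if self.control_point is None:
            zero = df.loc[df["zn_added"] == 0.0, "point_index"]
            if zero.empty:
                raise ValidationError("no zero-Zn control point in table")
            self.control_point = int(zero.min())
        ctrl = df[df["point_index"] == self.control_point]
        if ctrl.empty or (ctrl["zn_added"] != 0.0).any():
            raise ValidationError("control point must exist and have zn_added = 0")
        self.data = df.reset_index(drop=True)

    @property
    def peak_ids(self) -> list[str]:
        return list(pd.unique(self.data["peak_id"]))

    @property
    def point_indices(self) -> list[int]:
        return sorted(int(i) for i in pd.unique(self.data["point_index"]))

    def pivot(self, column: str = "intensity") -> pd.DataFrame:
        """Peaks x points matrix of the requested column."""
        return self.data.pivot(index="peak_id", columns="point_index", values=column)


@dataclass
class ApoSeries:
    """Apo-protein concentration per titration point with propagated error.

    ``data`` columns: ``point_index, zn_added, time_h, apo, error, n_peaks``
    (concentrations in μM).
    """

    data: pd.DataFrame
    control_conc: float

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        required = ["point_index", "zn_added", "time_h", "apo", "error", "n_peaks"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"apo series missing columns: {missing}")
        if (df["error"] < 0).any():
            raise ValidationError("errors must be >= 0")
        self.data = df.sort_values("point_index").reset_index(drop=True)
        self.control_conc = float(self.control_conc)

    @property
    def apo(self) -> np.ndarray:
        return self.data["apo"].to_numpy(float)

    @property
    def error(self) -> np.ndarray:
        return self.data["error"].to_numpy(float)

    @property
    def zn_added(self) -> np.ndarray:
        return self.data["zn_added"].to_numpy(float)


def select_peaks(table: PeakTable, snr_min: float = 4.0) -> list[str]:
    """Peaks that are distinct and exceed ``snr_min`` at every titration point.

    Order of first appearance in the table is preserved.  Raises
    :class:`SelectionError` (naming the failing criterion per peak) when no
    peak survives.
    """
    snr = table.pivot("intensity") / table.pivot("noise")
    distinct = table.data.groupby("peak_id", sort=False)["distinct"].all()
    selected: list[str] = []
    reasons: dict[str, str] = {}
    for peak in table.peak_ids:
        if not bool(distinct.loc[peak]):
            reasons[peak] = "not flagged as a distinct peak"
            continue
        worst = float(snr.loc[peak].min())
        if not worst > snr_min:
            reasons[peak] = f"SNR {worst:.3g} <= {snr_min:g} at some titration point"
            continue
        selected.append(peak)
    if not selected:
        detail = "; ".join(f"{p}: {r}" for p, r in reasons.items())
        raise SelectionError(f"no peak passed selection ({detail})", reasons)
    return selected


def apo_concentration(
    table: PeakTable,
    peaks: list[str] | None = None,
    drift_per_h: float | None = None,
) -> ApoSeries:
    """Apo-protein concentration per point from peak-intensity ratios.

    Per peak and point, apo = control_conc * I / I_control; the series value
    is the arithmetic mean over peaks and the error the sample standard
    deviation.  When ``drift_per_h`` is given, intensities are detrended by
    ``1/(1 - drift*t)`` and the sedimentation allowance
    ``|drift| * t * control_conc`` is added to the error.

    Negative or super-stoichiometric per-peak values caused by noise are
    retained (the estimator stays unbiased); clip at reporting time instead.
    """
    if peaks is None:
        peaks = select_peaks(table)
    unknown = set(peaks) - set(table.peak_ids)
    if unknown:
        raise ValidationError(f"peaks not present in table: {sorted(unknown)}")
    intensities = table.pivot("intensity").loc[list(peaks)]
    control = intensities[table.control_point]
    if (control <= 0).any():
        bad = control[control <= 0].index.tolist()
        raise ValidationError(f"control intensity <= 0 for peaks: {bad}")
    ratios = intensities.div(control, axis=0)

    meta = (
        table.data[["point_index", "zn_added", "time_h"]]
        .drop_duplicates("point_index")
        .set_index("point_index")
        .sort_index()
    )
    rows = []
    for point in ratios.columns:
        vals = table.control_conc * ratios[point].to_numpy(float)
        t = float(meta.loc[point, "time_h"])
        if drift_per_h is not None:
            decay = 1.0 - drift_per_h * t
            if decay <= 0:
                raise ValidationError("drift correction exceeds 100% signal loss")
            vals = vals / decay
        err = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        if drift_per_h is not None:
            err += abs(drift_per_h) * t * table.control_conc
        rows.append(
            {
                "point_index": int(point),
                "zn_added": float(meta.loc[point, "zn_added"]),
                "time_h": t,
                "apo": float(np.mean(vals)),
                "error": err,
                "n_peaks": len(vals),
            }
        )
    return ApoSeries(pd.DataFrame(rows), control_conc=table.control_conc)


def sedimentation_correction(
    zero_zn_series: PeakTable,
) -> tuple[float, pd.DataFrame]:
    """Sedimentation drift from a zero-Zn time series.

    Fits a least-squares line to the mean normalized intensity versus time
    and returns ``(drift_per_h, corrections)`` where ``drift_per_h`` is the
    fractional signal loss per hour (positive for decaying signal) and
    ``corrections`` has per-point columns ``point_index, time_h,
    correction`` with ``correction = |slope| * time_h * control_conc`` (μM).
    """
    df = zero_zn_series.data
    if (df["zn_added"] != 0.0).any():
        raise ValidationError("sedimentation series must be measured at zero Zn")
    mean_by_point = (
        df.groupby("point_index")
        .agg(time_h=("time_h", "first"), intensity=("intensity", "mean"))
        .sort_values("time_h")
    )
    times = mean_by_point["time_h"].to_numpy(float)
    if len(times) < 2:
        warnings.warn("single time point: sedimentation correction set to zero", stacklevel=2)
        out = mean_by_point.reset_index()[["point_index", "time_h"]]
        out["correction"] = 0.0
        return 0.0, out
    norm = mean_by_point["intensity"].to_numpy(float)
    norm = norm / norm[0]
    slope = float(np.polyfit(times, norm, 1)[0])
    drift = -slope
    out = mean_by_point.reset_index()[["point_index", "time_h"]]
    out["correction"] = abs(slope) * out["time_h"] * zero_zn_series.control_conc
    return drift, out


def chelator_bound(
    series: pd.DataFrame,
    c_total: float,
    ref_conc: float = DEFAULT_REF_CONC,
    calib: float = 1.0,
) -> pd.DataFrame:
    """Bound and free chelator per point from 1D reference/chelator ratios.

    ``series`` must have columns ``point_index, i_ref, i_chel``.  Bound
    chelator = ref_conc * calib * i_chel / i_ref, clipped to [0, c_total];
    free = c_total - bound.  All concentrations in μM.
    """
    if not c_total > 0:
        raise ValidationError("c_total must be > 0")
    df = pd.DataFrame(series).copy()
    missing = [c for c in CHELATOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"chelator table missing columns: {missing}")
    if (df["i_ref"] <= 0).any():
        raise ValidationError("reference intensity i_ref must be > 0")
    if (df["i_chel"] < 0).any():
        raise ValidationError("chelator intensity i_chel must be >= 0")
    bound = ref_conc * calib * df["i_chel"].to_numpy(float) / df["i_ref"].to_numpy(float)
    bound = np.clip(bound, 0.0, c_total)
    out = df[["point_index"]].copy()
    out["bound"] = bound
    out["free"] = c_total - bound
    return out
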