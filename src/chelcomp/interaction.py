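"""Protein-protein interaction screen by spectral intensity correlation and
apo-trajectory competition comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from chelcomp.errors import ValidationError
from chelcomp.inference import TTestResult
from chelcomp.intensity import ApoSeries, PeakTable


@dataclass(frozen=True)
class NormalizedSpectrum:
    """Peak intensities divided by a reference-peak intensity."""

    values: dict[str, float]
    reference_peak: str

    def __post_init__(self) -> None:
        ref = self.values.get(self.reference_peak)
        if ref is None:
            raise ValidationError(f"reference peak {self.reference_peak!r} not in spectrum")
        if not math.isclose(ref, 1.0, rel_tol=1e-9):
            raise ValidationError("reference peak must normalize to 1")
        if any(v < 0 for v in self.values.values()):
            raise ValidationError("normalized intensities must be >= 0")


@dataclass(frozen=True)
class CorrelationResult:
    """Zero-intercept regression slope and Pearson r between two spectra."""

    slope: float
    pearson_r: float
    n_peaks: int

    def __post_init__(self) -> None:
        if self.n_peaks < 3:
            raise ValidationError("n_peaks must be >= 3")
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValidationError("pearson_r out of [-1, 1]")


def normalize_to_reference(
    table: PeakTable, reference_peak: str
) -> dict[int, NormalizedSpectrum]:
    """Normalize each titration point's intensities to the reference peak.

    Removes the concentration uncertainty between samples; returns a mapping
    point_index -> :class:`NormalizedSpectrum`.
    """
    intensities = table.pivot("intensity")
    if reference_peak not in intensities.index:
        raise ValidationError(f"reference peak {reference_peak!r} missing from table")
    out: dict[int, NormalizedSpectrum] = {}
    for point in intensities.columns:
        ref = float(intensities.loc[reference_peak, point])
        if not ref > 0:
            raise ValidationError(
                f"reference peak {reference_peak!r} has non-positive intensity at point {point}"
            )
        values = {
            str(peak): float(intensities.loc[peak, point]) / ref for peak in intensities.index
        }
        out[int(point)] = NormalizedSpectrum(values=values, reference_peak=reference_peak)
    return out


def correlate_spectra(
    a: NormalizedSpectrum | dict[str, float],
    b: NormalizedSpectrum | dict[str, float],
) -> CorrelationResult:
    """Correlate two spectra over their shared peaks.

    Accepts :class:`NormalizedSpectrum` objects or plain peak -> intensity
    mappings.  Reports the zero-intercept least-squares slope of ``b`` on
    ``a`` and the standard Pearson correlation coefficient.
    """
    va = a.values if isinstance(a, NormalizedSpectrum) else dict(a)
    vb = b.values if isinstance(b, NormalizedSpectrum) else dict(b)
    shared = sorted(set(va) & set(vb))
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared peaks, got {len(shared)}")
    x = np.array([va[p] for p in shared])
    y = np.array([vb[p] for p in shared])
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValidationError("degenerate spectrum: all intensities zero")
    slope = float(np.dot(x, y) / sxx)
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(slope=slope, pearson_r=r, n_peaks=len(shared))


def compare_apo_trajectories(
    with_partner: ApoSeries,
    without_partner: ApoSeries,
    restriction: int = 2,
) -> pd.DataFrame:
    """Per-point pooled t comparison of two apo trajectories.

    Peaks act as replicates: per titration point the pooled two-sample t is
    built from the (mean, std-over-peaks, n_peaks) summaries of each series
    with ``df = n1 + n2 - restriction``.  A positive significant difference
    (more apo protein with the partner present) flags competition for the
    shared metal pool.  Returns one row per point with columns
    ``point_index, zn_added, delta_apo, t, df, p, stars, competition``.
    """
    da = with_partner.data
    db = without_partner.data
    if len(da) != len(db) or not np.array_equal(
        da["point_index"].to_numpy(), db["point_index"].to_numpy()
    ):
        raise ValidationError("titration points of the two series do not match")
    if not np.allclose(da["zn_added"], db["zn_added"]):
        raise ValidationError("zn_added values of the two series do not match")
    rows = []
    for ra, rb in zip(da.itertuples(), db.itertuples()):
        n1, n2 = int(ra.n_peaks), int(rb.n_peaks)
        if min(n1, n2) < 2:
            raise ValidationError("need >= 2 peaks per series for the pooled t-test")
        df_point = n1 + n2 - restriction
        pooled = ((n1 - 1) * ra.error**2 + (n2 - 1) * rb.error**2) / df_point
        delta = float(ra.apo - rb.apo)
        denom = math.sqrt(pooled * (1.0 / n1 + 1.0 / n2)) if pooled > 0 else 0.0
        if denom == 0.0:
            t = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
        else:
            t = delta / denom
        p = float(2.0 * stats.t.sf(abs(t), df_point)) if math.isfinite(t) else 0.0
        result = TTestResult(t=float(t), df=df_point, p=p, restriction=restriction)
        rows.append(
            {
                "point_index": int(ra.point_index),
                "zn_added": float(ra.zn_added),
                "delta_apo": delta,
                "t": result.t,
                "df": result.df,
                "p": result.p,
                "stars": result.stars,
                "competition": bool(delta > 0 and result.p < 0.05),
            }
        )
    return pd.DataFrame(rows)
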