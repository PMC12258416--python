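"""Shared fixtures and independent test oracles.

The bisection helpers here are deliberately written from scratch (plain
interval halving on the metal balance) so that solver checks do not share
code with the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chelcomp.intensity import PeakTable


def bisect_zn_balance(p, c, zn, kd_p, kd_c, iters=200):
    """Test-local bisection root of z + p*z/(kd_p+z) + c*z/(kd_c+z) = zn."""
    if zn == 0:
        return 0.0

    def g(z):
        return z + p * z / (kd_p + z) + c * z / (kd_c + z) - zn

    lo, hi = 0.0, zn
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def bisect_two_proteins(p1, kd1, p2, kd2, zn, iters=200):
    """Free fractions of two proteins sharing one Zn pool (test oracle)."""
    z = bisect_zn_balance(p1, p2, zn, kd1, kd2, iters)
    return 1.0 - z / (kd1 + z), 1.0 - z / (kd2 + z)


def make_peak_table(
    intensity_matrix,
    zn_points,
    control_conc=200.0,
    noise=2.0,
    distinct=True,
    time_per_point=1.0,
):
    """Build a PeakTable from a peaks x points intensity array."""
    intensity_matrix = np.asarray(intensity_matrix, dtype=float)
    n_peaks, n_points = intensity_matrix.shape
    assert n_points == len(zn_points)
    rows = []
    for j in range(n_peaks):
        for i in range(n_points):
            rows.append(
                {
                    "peak_id": f"peak{j + 1}",
                    "point_index": i,
                    "zn_added": float(zn_points[i]),
                    "time_h": i * time_per_point,
                    "intensity": intensity_matrix[j, i],
                    "noise": noise if np.isscalar(noise) else noise[j][i],
                    "distinct": distinct if np.isscalar(distinct) else distinct[j],
                }
            )
    return PeakTable(pd.DataFrame(rows), control_conc=control_conc, control_point=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20250303)


@pytest.fixture
def zn_grid():
    return (0.0, 12.5, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0)
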