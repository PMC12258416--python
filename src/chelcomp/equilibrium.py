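"""Mass-action equilibrium model for protein/chelator competition for Zn.

The three-component system (protein P, chelator C, metal Zn) is governed by
three conservation laws and two 1:1 binding isotherms:

    [PZn] + [P]  = P_total
    [CZn] + [C]  = C_total
    [Zn] + [PZn] + [CZn] = Zn_total
    [P][Zn]/[PZn] = Kd_P
    [C][Zn]/[CZn] = Kd_C

Substituting the isotherms into the metal balance collapses the system to a
single monotone scalar equation in free Zn,

    g(z) = z + P_total*z/(Kd_P+z) + C_total*z/(Kd_C+z) - Zn_total,

which is solved on the bracket [0, Zn_total].  All quantities are molar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from chelcomp.errors import ValidationError

#: Default chelator:Zn dissociation constant (molar): NTA, 4.4 nM.
DEFAULT_KD_CHELATOR = 4.4e-9

_PROTOCOL_MODES = ("zn_only", "premixed_chelator_zn")


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class CompetitionSystem:
    """Total concentrations and dissociation constants of the P/C/Zn system.

    All fields are in molar units.
    """

    p_total: float
    c_total: float
    zn_total: float
    kd_p: float
    kd_c: float = DEFAULT_KD_CHELATOR

    def __post_init__(self) -> None:
        for name in ("p_total", "c_total", "zn_total"):
            object.__setattr__(self, name, _require_finite_nonneg(name, getattr(self, name)))
        for name in ("kd_p", "kd_c"):
            value = float(getattr(self, name))
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {value!r}")
            object.__setattr__(self, name, value)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (molar) of all five species."""

    zn_free: float
    p_free: float
    pzn: float
    c_free: float
    czn: float


@dataclass(frozen=True)
class TitrationProtocol:
    """Ordered Zn-addition schedule.

    ``zn_only`` keeps the chelator total fixed; ``premixed_chelator_zn``
    adds chelator 1:1 with the metal on top of any pre-existing chelator,
    so the chelator total at point *i* equals ``base + zn_points[i]``.
    """

    mode: str
    zn_points: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mode not in _PROTOCOL_MODES:
            raise ValidationError(f"mode must be one of {_PROTOCOL_MODES}, got {self.mode!r}")
        pts = tuple(float(z) for z in self.zn_points)
        if not pts:
            raise ValidationError("zn_points must be non-empty")
        if pts[0] != 0.0:
            raise ValidationError("first titration point must be 0")
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise ValidationError("zn_points must be strictly increasing")
        object.__setattr__(self, "zn_points", pts)

    def chelator_totals(self, base_c_total: float) -> tuple[float, ...]:
        """Chelator total at every titration point (molar)."""
        base = _require_finite_nonneg("base_c_total", base_c_total)
        if self.mode == "zn_only":
            return tuple(base for _ in self.zn_points)
        return tuple(base + z for z in self.zn_points)


def _bound(total: float, kd: float, zn_free: float) -> float:
    return total * zn_free / (kd + zn_free)


def _zn_balance(zn_free: float, system: CompetitionSystem) -> float:
    return (
        zn_free
        + _bound(system.p_total, system.kd_p, zn_free)
        + _bound(system.c_total, system.kd_c, zn_free)
        - system.zn_total
    )


def _state_from_zn_free(system: CompetitionSystem, zn_free: float) -> SpeciesState:
    pzn = _bound(system.p_total, system.kd_p, zn_free)
    czn = _bound(system.c_total, system.kd_c, zn_free)
    return SpeciesState(
        zn_free=zn_free,
        p_free=system.p_total - pzn,
        pzn=pzn,
        c_free=system.c_total - czn,
        czn=czn,
    )


def solve_competition(system: CompetitionSystem) -> SpeciesState:
    """Solve the competition equilibrium; returns the unique physical root.

    The metal balance ``g`` is strictly increasing in free Zn with
    ``g(0) <= 0`` and ``g(Zn_total) >= 0``, so the bracketed root is unique.
    ``zn_free`` is exactly 0 when ``zn_total`` is 0.
    """
    if not isinstance(system, CompetitionSystem):
        system = CompetitionSystem(*system)
    if system.zn_total == 0.0:
        return _state_from_zn_free(system, 0.0)
    zn_free = brentq(
        _zn_balance,
        0.0,
        system.zn_total,
        args=(system,),
        xtol=1e-18 * system.zn_total,  # scale-relative: totals span many decades
        rtol=4 * 2.220446049250313e-16,
        maxiter=200,
    )
    return _state_from_zn_free(system, float(zn_free))


def oracle_solve(system: CompetitionSystem, rel_tol: float = 1e-12) -> SpeciesState:
    """Independent bisection solver for cross-checking :func:`solve_competition`.

    Plain interval halving on [0, Zn_total]; deliberately shares no root
    finding code with the main solver.
    """
    if rel_tol <= 0:
        raise ValidationError("rel_tol must be positive")
    if system.zn_total == 0.0:
        return _state_from_zn_free(system, 0.0)
    lo, hi = 0.0, system.zn_total
    # interval halving: ~60 iterations reach double precision on any scale
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _zn_balance(mid, system) > 0.0:
            hi = mid
        else:
            lo = mid
        if (hi - lo) <= rel_tol * system.zn_total:
            break
    return _state_from_zn_free(system, 0.5 * (lo + hi))


def free_fraction_curve(
    p_total: float,
    kd_p: float,
    protocol: TitrationProtocol,
    c_total: float = 0.0,
    kd_c: float = DEFAULT_KD_CHELATOR,
) -> list[tuple[float, float]]:
    """Free-protein fraction at every point of a titration protocol.

    ``c_total`` is the pre-existing chelator total; in premixed mode the
    chelator grows 1:1 with added Zn on top of it.  Returns a list of
    ``(zn_total, p_free/p_total)`` pairs in protocol order.
    """
    if p_total <= 0:
        raise ValidationError("p_total must be > 0")
    c_totals = protocol.chelator_totals(c_total)
    curve = []
    for zn, ct in zip(protocol.zn_points, c_totals):
        system = CompetitionSystem(p_total, ct, zn, kd_p, kd_c)
        state = solve_competition(system)
        curve.append((zn, state.p_free / p_total))
    return curve


def solve_two_proteins(
    p1_total: float,
    kd1: float,
    p2_total: float,
    kd2: float,
    zn_total: float,
) -> tuple[float, float, float]:
    """Two proteins competing for one Zn pool (no chelator).

    Reuses the monotone scalar balance with the chelator slot holding the
    second protein.  Returns ``(zn_free, frac1_free, frac2_free)``.
    """
    system = CompetitionSystem(p1_total, p2_total, zn_total, kd1, kd2)
    state = solve_competition(system)
    frac1 = state.p_free / p1_total if p1_total > 0 else 1.0
    frac2 = state.c_free / p2_total if p2_total > 0 else 1.0
    return state.zn_free, frac1, frac2
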