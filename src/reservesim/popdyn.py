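"""Delay-difference biomass dynamics for a single species on a patch grid.

The operating model is the Deriso-Schnute delay-difference recursion, which
collapses age structure into two classes (recruits and adults) while keeping
a one-year memory of survival and biomass so that individual growth (Brody
coefficient ``rho``) and recruitment enter with the correct lags:

    B[t+1] = (1+rho)*s[t]*B[t] - rho*s[t]*s[t-1]*B[t-1]
             - rho*s[t]*w_km1*R[t] + w_k*R[t+1]

where ``B`` is biomass after adult movement, ``s`` is total annual survival
(natural survival times survival from fishing), ``w_k`` / ``w_km1`` are the
mean weights of adults and recruits, and ``R`` is recruitment in numbers.
All biomass is carried in grams; recruitment in individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesParams",
    "PopState",
    "annual_survival",
    "step_biomass",
    "unfished_equilibrium",
    "equilibrium_under_harvest",
    "yield_curve",
    "msy_harvest_rate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesParams:
    """Biological and economic constants for one species.

    Parameters
    ----------
    name
        Species label.
    s_nat
        Annual natural survival fraction, in [0, 1].
    w_k
        Mean weight (g) of an animal of reproductive age ``k`` and older.
    w_km1
        Mean weight (g) of recruits (age ``k-1``); zero for species whose
        recruits carry negligible biomass.
    rho
        Brody growth coefficient in [0, 1); controls individual growth.
    R0
        Unfished recruitment per patch (individuals/year).
    sigma_L
        Larval dispersal range in patch-length units (> 0).
    sigma_A
        Adult movement range in patch-length units (> 0).
    h
        Beverton-Holt steepness in (0.2, 1]: the fraction of unfished
        recruitment produced when spawning output drops to 20% of its
        unfished level.
    price
        Landed value per gram of catch (currency/g).
    role
        Either ``"fished"`` (contributes to fishery profit) or ``"tourism"``
        (its in-reserve biomass drives dive demand).
    """

    name: str
    s_nat: float
    w_k: float
    w_km1: float
    rho: float
    R0: float
    sigma_L: float
    sigma_A: float
    h: float
    price: float = 0.0
    role: str = "fished"

    def __post_init__(self) -> None:
        checks = [
            ("s_nat", 0.0 <= self.s_nat <= 1.0, "must be in [0, 1]"),
            ("rho", 0.0 <= self.rho < 1.0, "must be in [0, 1)"),
            ("h", 0.2 < self.h <= 1.0, "must be in (0.2, 1]"),
            ("w_k", self.w_k > 0, "must be > 0"),
            ("w_km1", self.w_km1 >= 0, "must be >= 0"),
            ("R0", self.R0 >= 0, "must be >= 0"),
            ("sigma_L", self.sigma_L > 0, "must be > 0"),
            ("sigma_A", self.sigma_A > 0, "must be > 0"),
            ("price", self.price >= 0, "must be >= 0"),
            ("role", self.role in ("fished", "tourism"), "must be 'fished' or 'tourism'"),
        ]
        for pname, ok, msg in checks:
            if not ok:
                raise ValueError(
                    f"SpeciesParams.{pname}={getattr(self, pname)!r} {msg}"
                )


@dataclass
class PopState:
    """Per-patch state of the delay-difference recursion.

    ``B`` and ``B_prev`` are biomass *after adult movement* in the current
    and previous year; ``R`` is this year's recruitment, ``R_next`` the
    recruitment entering next year; ``s_prev`` is the realized survival
    applied in the previous year.
    """

    B: np.ndarray
    B_prev: np.ndarray
    R: np.ndarray
    R_next: np.ndarray
    s_prev: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for fname in ("B", "B_prev", "R", "R_next", "s_prev"):
            arrays[fname] = np.asarray(getattr(self, fname), dtype=float)
            setattr(self, fname, arrays[fname])
        n = arrays["B"].shape
        for fname, arr in arrays.items():
            if arr.shape != n:
                raise ValueError(
                    f"PopState.{fname} has shape {arr.shape}, expected {n}"
                )
        for fname in ("B", "B_prev", "R", "R_next"):
            if np.any(arrays[fname] < 0):
                raise ValueError(f"PopState.{fname} contains negative entries")

    @property
    def n_patches(self) -> int:
        return self.B.shape[0]


def annual_survival(s_nat: float, u) -> np.ndarray | float:
    """Total annual survival: natural survival times survival from fishing.

    ``u`` is the harvest rate (fraction of post-movement biomass removed),
    scalar or per patch; fishing survival is ``1 - u``.
    """
    if not 0.0 <= s_nat <= 1.0:
        raise ValueError(f"s_nat={s_nat!r} must be in [0, 1]")
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0) or np.any(u_arr > 1):
        raise ValueError(f"u={u!r} must be in [0, 1]")
    out = s_nat * (1.0 - u_arr)
    return float(out) if np.isscalar(u) or u_arr.ndim == 0 else out


def step_biomass(state: PopState, params: SpeciesParams, s_now) -> np.ndarray:
    """One year of the delay-difference recursion; returns next year's biomass.

    The caller is responsible for rotating the lags afterwards
    (``B_prev <- B``, ``R <- R_next``, ``s_prev <- s_now``).  Transient
    negative biomass (possible under extreme parameter combinations because
    of the lag term) is clamped to zero and logged rather than raised.
    """
    s = np.asarray(s_now, dtype=float)
    if s.shape != state.B.shape:
        raise ValueError(f"s_now has shape {s.shape}, expected {state.B.shape}")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("s_now entries must be in [0, 1]")
    rho = params.rho
    b_next = (
        (1.0 + rho) * s * state.B
        - rho * s * state.s_prev * state.B_prev
        - rho * s * params.w_km1 * state.R
        + params.w_k * state.R_next
    )
    neg = b_next < 0
    if np.any(neg):
        logger.warning(
            "step_biomass: clamped %d negative patch biomass value(s) to 0 "
            "(min %.3g g)", int(neg.sum()), float(b_next.min()),
        )
        b_next = np.where(neg, 0.0, b_next)
    return b_next


def unfished_equilibrium(params: SpeciesParams) -> float:
    """Stationary per-patch biomass (g) with recruitment ``R0`` and no fishing.

    Closed form of the recursion's fixed point with survival ``s_nat``:
    ``B0 = (w_k - rho*s_nat*w_km1) * R0 / ((1 - s_nat)(1 - rho*s_nat))``.
    """
    s = params.s_nat
    denom = (1.0 - s) * (1.0 - params.rho * s)
    if denom <= 0:
        raise ValueError(
            f"degenerate equilibrium denominator for s_nat={s}: "
            "(1 - s_nat)(1 - rho*s_nat) must be > 0"
        )
    return (params.w_k - params.rho * s * params.w_km1) * params.R0 / denom


def _beverton_holt_scalar(E: float, h: float, R0: float, E0: float) -> float:
    # local copy to avoid a circular import with the spatial module
    return (4.0 * h * R0 * E) / ((1.0 - h) * E0 + (5.0 * h - 1.0) * E) if E > 0 else 0.0


def equilibrium_under_harvest(
    params: SpeciesParams, u: float, years: int = 500
) -> float:
    """Long-run per-patch biomass under a constant harvest rate.

    Iterates the single-patch (well-mixed, identity-kernel) model with
    Beverton-Holt recruitment anchored at the unfished equilibrium.  Used by
    the MSY search and as the iterated oracle for the closed form.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u={u!r} must be in [0, 1]")
    b0 = unfished_equilibrium(params)
    if b0 == 0:
        return 0.0
    s = annual_survival(params.s_nat, u)
    b = b_prev = b0
    r = r_next = params.R0
    s_prev = s
    rho = params.rho
    for _ in range(years):
        r_next = _beverton_holt_scalar(b, params.h, params.R0, b0)
        b_new = (
            (1.0 + rho) * s * b
            - rho * s * s_prev * b_prev
            - rho * s * params.w_km1 * r
            + params.w_k * r_next
        )
        b_prev, b, r, s_prev = b, max(b_new, 0.0), r_next, s
    return b


def yield_curve(
    params: SpeciesParams, u_grid: np.ndarray, years: int = 500
) -> np.ndarray:
    """Equilibrium annual yield ``u * B_eq(u)`` (g) on a grid of harvest rates."""
    u_grid = np.asarray(u_grid, dtype=float)
    return np.array(
        [u * equilibrium_under_harvest(params, float(u), years) for u in u_grid]
    )


def msy_harvest_rate(
    params: SpeciesParams, u_max: float = 0.95, n_grid: int = 96, years: int = 500
) -> float:
    """Harvest rate maximizing long-run equilibrium yield, by grid search.

    The grid search over [0, u_max] is refined once around the coarse
    optimum with a 10x finer grid.
    """
    grid = np.linspace(0.0, u_max, n_grid)
    yields = yield_curve(params, grid, years=years)
    i = int(np.argmax(yields))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    fine = np.linspace(lo, hi, 41)
    fine_yields = yield_curve(params, fine, years=years)
    return float(fine[int(np.argmax(fine_yields))])
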