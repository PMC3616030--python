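"""Fishery profit and dive-tourism economics.

The fishery layer values catch at a per-gram price net of a per-patch cost
per unit of fishing effort (effort is taken equal to the harvest rate).  The
tourism layer uses a linear inverse demand for dives in the reserve,

    MV(q) = alpha + beta*q + gamma*B,       beta < 0, gamma >= 0,

where ``B`` is the biomass of the tourism species inside the reserve: the
marginal value of a dive falls with the number of dives and rises linearly
with the fish biomass divers can expect to see.  Revenue is fee*q; consumer
surplus is the area under the demand line above the fee.  Because the
demand parameters for a real site are rarely published, a deterministic
calibration routine recovers (alpha, beta, gamma) from interpretable
quantities: the dives observed at a known fee, the choke-price multiple,
and the share of the choke price attributable to biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TourismParams",
    "EconParams",
    "catch",
    "fishery_profit",
    "marginal_dive_value",
    "dives_demanded",
    "optimal_dives",
    "optimal_fee",
    "tourism_revenue",
    "consumer_surplus",
    "calibrate_demand",
]

FEE_POLICIES = ("fixed", "optimal", "capped")


@dataclass(frozen=True)
class TourismParams:
    """Linear inverse-demand parameters plus the fee/cap policy.

    ``alpha`` is the demand intercept (currency/dive), ``beta < 0`` the slope
    in dives (currency/dive^2), ``gamma >= 0`` the biomass sensitivity
    (currency/dive/gram).  ``fee_policy`` selects how the annual fee is set:
    ``fixed`` charges ``fixed_fee``; ``optimal`` charges the revenue-
    maximizing fee each year; ``capped`` charges ``fixed_fee`` with dives
    limited to ``cap`` (``cap`` may be None until a cap event fires).
    """

    alpha: float
    beta: float
    gamma: float
    fee_policy: str = "fixed"
    fixed_fee: float = 0.0
    cap: float | None = None

    def __post_init__(self) -> None:
        if self.beta >= 0:
            raise ValueError(f"TourismParams.beta={self.beta!r} must be < 0")
        if self.gamma < 0:
            raise ValueError(f"TourismParams.gamma={self.gamma!r} must be >= 0")
        if self.fee_policy not in FEE_POLICIES:
            raise ValueError(
                f"TourismParams.fee_policy={self.fee_policy!r} "
                f"must be one of {FEE_POLICIES}"
            )
        if self.fixed_fee < 0:
            raise ValueError(f"TourismParams.fixed_fee={self.fixed_fee!r} must be >= 0")
        if self.cap is not None and self.cap < 0:
            raise ValueError(f"TourismParams.cap={self.cap!r} must be >= 0")


@dataclass(frozen=True)
class EconParams:
    """Fishery cost structure: per-patch cost per unit effort (effort = u)."""

    cost: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cost, dtype=float)
        object.__setattr__(self, "cost", c)
        if np.any(c < 0):
            raise ValueError("EconParams.cost entries must be >= 0")


def catch(u, B_moved) -> np.ndarray:
    """Per-patch catch ``C_i = u_i * B~_i`` (g), from post-movement biomass."""
    u_arr = np.asarray(u, dtype=float)
    b = np.asarray(B_moved, dtype=float)
    if u_arr.shape != b.shape:
        raise ValueError(f"u has shape {u_arr.shape}, B_moved {b.shape}")
    if np.any(u_arr < 0) or np.any(u_arr > 1):
        raise ValueError("harvest rates must be in [0, 1]")
    return u_arr * b


def fishery_profit(C, u, price: float, econ: EconParams) -> float:
    """Annual fishery profit ``sum_i (price*C_i - cost_i*u_i)``; may be negative."""
    c_arr = np.asarray(C, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if not (c_arr.shape == u_arr.shape == econ.cost.shape):
        raise ValueError(
            f"shape mismatch: C {c_arr.shape}, u {u_arr.shape}, cost {econ.cost.shape}"
        )
    return float(np.sum(price * c_arr - econ.cost * u_arr))


def marginal_dive_value(q: float, B: float, t: TourismParams) -> float:
    """Marginal value of the q-th dive at reserve biomass ``B`` (linear demand)."""
    return t.alpha + t.beta * q + t.gamma * B


def choke_price(B: float, t: TourismParams) -> float:
    """Fee at which demand falls to zero: the demand intercept at biomass B."""
    return t.alpha + t.gamma * B


def dives_demanded(fee: float, B: float, t: TourismParams) -> float:
    """Dives demanded at a given fee, from inverting the demand line.

    ``q = (fee - alpha - gamma*B) / beta``, truncated at zero when the fee
    exceeds the choke price.
    """
    return max(0.0, (fee - t.alpha - t.gamma * B) / t.beta)


def optimal_dives(B: float, t: TourismParams) -> float:
    """Revenue-maximizing number of dives, ``q* = -(alpha + gamma*B)/(2 beta)``."""
    return max(0.0, -(t.alpha + t.gamma * B) / (2.0 * t.beta))


def optimal_fee(B: float, t: TourismParams) -> float:
    """Revenue-maximizing fee, ``P* = (alpha + gamma*B)/2`` (half the choke price)."""
    return max(0.0, (t.alpha + t.gamma * B) / 2.0)


def tourism_revenue(fee: float, q: float) -> float:
    """Annual fee revenue, ``fee * q``."""
    return fee * q


def consumer_surplus(fee: float, q: float, B: float, t: TourismParams) -> float:
    """Surplus of the ``q`` dives taken at ``fee``: area under the demand line
    above the fee, ``(alpha + gamma*B - fee)*q + beta*q^2/2``.

    ``q`` must not exceed demand at the fee (otherwise the marginal diver
    values the dive below what they pay).  Under a binding cap this is the
    surplus of the capped dives at the fixed fee.
    """
    if q < 0:
        raise ValueError(f"q={q!r} must be >= 0")
    q_max = dives_demanded(fee, B, t)
    if q > q_max * (1 + 1e-9) + 1e-9:
        raise ValueError(
            f"q={q} exceeds dives demanded at fee {fee} (={q_max}); "
            "consumer surplus is undefined"
        )
    return (t.alpha + t.gamma * B - fee) * q + t.beta * q**2 / 2.0


def calibrate_demand(
    target_dives: float,
    fee: float,
    B_ref: float,
    choke_multiple: float = 2.0,
    biomass_share: float = 0.5,
    fee_policy: str = "fixed",
    fixed_fee: float | None = None,
) -> TourismParams:
    """Recover (alpha, beta, gamma) from interpretable calibration inputs.

    Constructs the unique linear demand such that exactly ``target_dives``
    are demanded at ``fee`` when the reserve biomass is ``B_ref``, the choke
    price at ``B_ref`` equals ``choke_multiple * fee``, and the biomass term
    ``gamma * B_ref`` contributes ``biomass_share`` of that choke price.
    Deterministic; raises on infeasible combinations.
    """
    if target_dives <= 0:
        raise ValueError(f"target_dives={target_dives!r} must be > 0")
    if fee <= 0:
        raise ValueError(f"fee={fee!r} must be > 0")
    if choke_multiple <= 1:
        raise ValueError(
            f"choke_multiple={choke_multiple!r} must be > 1 (the observed fee "
            "must sit below the choke price for demand to be positive)"
        )
    if not 0.0 <= biomass_share < 1.0:
        raise ValueError(f"biomass_share={biomass_share!r} must be in [0, 1)")
    if biomass_share > 0 and B_ref <= 0:
        raise ValueError(
            "biomass_share > 0 requires B_ref > 0 to attribute part of the "
            "choke price to biomass"
        )
    choke = choke_multiple * fee
    gamma = biomass_share * choke / B_ref if biomass_share > 0 else 0.0
    alpha = choke - gamma * B_ref
    beta = (fee - choke) / target_dives
    return TourismParams(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        fee_policy=fee_policy,
        fixed_fee=fee if fixed_fee is None else fixed_fee,
    )
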