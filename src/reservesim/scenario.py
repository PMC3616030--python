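"""Scenario engine: burn-in, reserve creation, management events, economics.

A scenario runs each species independently on the shared coastline for
``burn_in_years`` under uniform pre-reserve harvest, then creates the zoned
reserve at year 0 (harvest drops to zero in the no-take zone, is cut by
``partial_reduction`` in the partial zone, and is unchanged outside) and
runs ``post_years`` more.  Each simulated year applies, in a fixed order:
adult movement, catch and survival, egg production (equal to start-of-year
spawning biomass) with larval dispersal and settlement, Beverton-Holt
recruitment, and the delay-difference biomass update.  The economic layer
then records fishery profit from the fished species, dive demand from the
tourism species' biomass inside the reserve under the active fee policy,
fee revenue, consumer surplus, and total value.  The whole simulation is
deterministic given its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import economics, popdyn, spatial
from .economics import EconParams, TourismParams, calibrate_demand
from .popdyn import PopState, SpeciesParams
from .spatial import Coastline

__all__ = [
    "SpeciesSetup",
    "DemandCalibration",
    "ManagementEvent",
    "ScenarioConfig",
    "ScenarioResult",
    "build_zones",
    "apply_reserve",
    "run_simulation",
    "payback_year",
]


@dataclass(frozen=True)
class SpeciesSetup:
    """A species together with its uniform pre-reserve harvest rate."""

    params: SpeciesParams
    u_pre: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_pre <= 1.0:
            raise ValueError(
                f"u_pre={self.u_pre!r} for species {self.params.name!r} "
                "must be in [0, 1]"
            )


@dataclass(frozen=True)
class DemandCalibration:
    """Inputs from which tourism demand parameters are derived at run time.

    The reference biomass is the tourism species' biomass in the reserve
    zone at its fully protected (unfished) equilibrium, computed from the
    scenario itself, so the calibration needs no biomass input.
    """

    target_dives: float
    fee: float
    choke_multiple: float = 2.0
    biomass_share: float = 0.5
    fee_policy: str = "fixed"


@dataclass(frozen=True)
class ManagementEvent:
    """A policy change firing at a given post-reserve year (index 0 = reserve
    creation).  The only supported action is ``cap_dives``: switch to the
    capped fee policy at ``fee`` with the cap set to that year's demand."""

    year: int
    action: str = "cap_dives"
    fee: float = 3.5

    def __post_init__(self) -> None:
        if self.year < 0:
            raise ValueError(f"event year={self.year} must be >= 0 (post-reserve)")
        if self.action != "cap_dives":
            raise ValueError(f"unknown event action {self.action!r}")
        if self.fee < 0:
            raise ValueError(f"event fee={self.fee} must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one deterministic scenario."""

    species: tuple[SpeciesSetup, ...]
    n_patches: int = 100
    patch_length: float = 1.0
    fractions: tuple[float, float, float] = (0.01, 0.12, 0.87)
    burn_in_years: int = 100
    post_years: int = 100
    partial_reduction: float = 0.5
    cost_per_effort: float = 0.0
    tourism: TourismParams | DemandCalibration | None = None
    events: tuple[ManagementEvent, ...] = ()
    include_partial_in_reserve: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "fractions", tuple(float(f) for f in self.fractions))
        if not self.species:
            raise ValueError("at least one species is required")
        names = [s.params.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate species names: {names}")
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be three non-negative numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions {self.fractions} must sum to 1")
        if self.burn_in_years < 1 or self.post_years < 1:
            raise ValueError("burn_in_years and post_years must be >= 1")
        if not 0.0 <= self.partial_reduction <= 1.0:
            raise ValueError(
                f"partial_reduction={self.partial_reduction} must be in [0, 1]"
            )
        if self.cost_per_effort < 0:
            raise ValueError(f"cost_per_effort={self.cost_per_effort} must be >= 0")


@dataclass
class ScenarioResult:
    """Annual series and per-patch states produced by one scenario run."""

    years: np.ndarray  # negative = pre-reserve
    fv: np.ndarray  # fishery profit
    dives: np.ndarray
    fee: np.ndarray
    tr: np.ndarray  # tourism (fee) revenue
    cs: np.ndarray  # consumer surplus
    coast: Coastline
    biomass: dict[str, np.ndarray]  # species -> (n_years, n_patches), post-movement
    catch: dict[str, np.ndarray]
    reserve_biomass: np.ndarray  # tourism biomass driving dive demand, per year
    tourism_final: TourismParams | None
    events_fired: list[str] = field(default_factory=list)
    audit: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def tv(self) -> np.ndarray:
        """Total value: fishery profit + fee revenue + consumer surplus."""
        return self.fv + self.tr + self.cs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "FV": self.fv,
                "dives": self.dives,
                "fee": self.fee,
                "TR": self.tr,
                "CS": self.cs,
                "TV": self.tv,
            }
        )

    def biomass_frame(self) -> pd.DataFrame:
        """Long-format per-patch biomass and catch, one row per
        year x species x patch."""
        frames = []
        for name, b in self.biomass.items():
            n_years, n_patches = b.shape
            frames.append(
                pd.DataFrame(
                    {
                        "year": np.repeat(self.years, n_patches),
                        "species": name,
                        "patch": np.tile(np.arange(n_patches), n_years),
                        "biomass": b.ravel(),
                        "catch": self.catch[name].ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def build_zones(
    n_patches: int,
    fractions: tuple[float, float, float],
    patch_length: float = 1.0,
) -> Coastline:
    """Zone the coastline: a centered no-take block, a partial-protection zone
    split symmetrically around it, and open access elsewhere.

    Patch counts come from the fractions by largest-remainder rounding, so
    they always sum to ``n_patches``.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions} must be 3 non-negatives summing to 1")
    raw = fr * n_patches
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder, kind="stable")[: n_patches - counts.sum()]:
        counts[i] += 1
    c_nt, c_pa, _ = (int(c) for c in counts)

    zone = np.array(["open"] * n_patches, dtype=object)
    start = n_patches // 2 - c_nt // 2
    zone[start : start + c_nt] = "no_take"
    left = c_pa // 2
    right = c_pa - left
    zone[max(start - left, 0) : start] = "partial"
    zone[start + c_nt : start + c_nt + right] = "partial"
    # if the blocks overrun an edge, push the overflow to the other side
    placed = int(np.sum(zone == "partial"))
    if placed < c_pa:
        for i in range(n_patches):
            if placed == c_pa:
                break
            if zone[i] == "open":
                zone[i] = "partial"
                placed += 1
    return Coastline(n_patches=n_patches, patch_length=patch_length, zone=tuple(zone))


def apply_reserve(
    u_pre: float, coast: Coastline, partial_reduction: float = 0.5
) -> np.ndarray:
    """Post-reserve per-patch harvest rates: zero in the no-take zone,
    ``u_pre * (1 - partial_reduction)`` in the partial zone, ``u_pre`` outside."""
    if not 0.0 <= u_pre <= 1.0:
        raise ValueError(f"u_pre={u_pre!r} must be in [0, 1]")
    if not 0.0 <= partial_reduction <= 1.0:
        raise ValueError(f"partial_reduction={partial_reduction!r} must be in [0, 1]")
    u = np.full(coast.n_patches, u_pre)
    u[coast.zone_mask("no_take")] = 0.0
    u[coast.zone_mask("partial")] = u_pre * (1.0 - partial_reduction)
    return u


def resolve_tourism(config: ScenarioConfig, coast: Coastline) -> TourismParams | None:
    """Turn the config's tourism spec into concrete demand parameters.

    A :class:`DemandCalibration` is anchored at the reserve-zone biomass of
    the tourism species at their unfished equilibrium (per-patch equilibrium
    times the number of reserve patches).
    """
    t = config.tourism
    if t is None or isinstance(t, TourismParams):
        return t
    mask = coast.zone_mask("no_take")
    if config.include_partial_in_reserve:
        mask = mask | coast.zone_mask("partial")
    n_res = int(mask.sum())
    b_ref = sum(
        popdyn.unfished_equilibrium(s.params) * n_res
        for s in config.species
        if s.params.role == "tourism"
    )
    return calibrate_demand(
        target_dives=t.target_dives,
        fee=t.fee,
        B_ref=b_ref,
        choke_multiple=t.choke_multiple,
        biomass_share=t.biomass_share,
        fee_policy=t.fee_policy,
    )


def _annual_economics(
    t: TourismParams, b_reserve: float
) -> tuple[float, float, float, float]:
    """(fee, dives, revenue, consumer surplus) for one year under policy ``t``."""
    if t.fee_policy == "optimal":
        fee = economics.optimal_fee(b_reserve, t)
        q = economics.optimal_dives(b_reserve, t)
    else:
        fee = t.fixed_fee
        q = economics.dives_demanded(fee, b_reserve, t)
        if t.fee_policy == "capped" and t.cap is not None:
            q = min(q, t.cap)
    return fee, q, economics.tourism_revenue(fee, q), economics.consumer_surplus(
        fee, q, b_reserve, t
    )


def run_simulation(config: ScenarioConfig) -> ScenarioResult:
    """Run one scenario end to end; see the module docstring for the yearly
    operation order.  Raises ``RuntimeError`` with a year/patch diagnostic if
    the state ever becomes non-finite."""
    coast = build_zones(config.n_patches, config.fractions, config.patch_length)
    n = coast.n_patches
    n_years = config.burn_in_years + config.post_years
    years = np.arange(-config.burn_in_years, config.post_years)

    reserve_mask = coast.zone_mask("no_take")
    if config.include_partial_in_reserve:
        reserve_mask = reserve_mask | coast.zone_mask("partial")

    tourism = resolve_tourism(config, coast)
    econ = EconParams(cost=np.full(n, config.cost_per_effort))

    # per-species static structures
    sims = []
    for setup in config.species:
        p = setup.params
        k_l = spatial.dispersal_matrix(coast, p.sigma_L)
        k_a = spatial.dispersal_matrix(coast, p.sigma_A)
        b0 = popdyn.unfished_equilibrium(p)
        b0_vec = np.full(n, b0)
        b0_moved = spatial.move_adults(b0_vec, k_a)
        e0 = spatial.settle_larvae(b0_moved, k_l)  # unfished settlement, per patch
        state = PopState(
            B=b0_vec.copy(),  # start-of-year biomass; moved within the loop
            B_prev=b0_moved.copy(),
            R=np.full(n, p.R0),
            R_next=np.full(n, p.R0),
            s_prev=np.full(n, p.s_nat),
        )
        u_pre_vec = np.full(n, setup.u_pre)
        u_post_vec = apply_reserve(setup.u_pre, coast, config.partial_reduction)
        sims.append(
            {"p": p, "k_l": k_l, "k_a": k_a, "e0": e0, "state": state,
             "u_pre": u_pre_vec, "u_post": u_post_vec}
        )

    biomass = {s["p"].name: np.empty((n_years, n)) for s in sims}
    catches = {s["p"].name: np.empty((n_years, n)) for s in sims}
    audit = {
        s["p"].name: {k: np.empty((n_years, n)) for k in
                      ("growth", "lag", "recruit_drag", "recruit_add", "b_next")}
        for s in sims
    }
    fv = np.empty(n_years)
    dives = np.empty(n_years)
    fee_series = np.empty(n_years)
    tr = np.empty(n_years)
    cs = np.empty(n_years)
    reserve_b = np.empty(n_years)
    events_fired: list[str] = []
    events_by_year = {ev.year: ev for ev in config.events}

    for idx, year in enumerate(years):
        post = year >= 0
        fv_year = 0.0
        b_res = 0.0
        for s in sims:
            p: SpeciesParams = s["p"]
            state: PopState = s["state"]
            u = s["u_post"] if post else s["u_pre"]

            b_moved = spatial.move_adults(state.B, s["k_a"])
            c = economics.catch(u, b_moved)
            s_now = popdyn.annual_survival(p.s_nat, u)

            eggs = b_moved  # egg output equals start-of-year spawning biomass
            settled = spatial.settle_larvae(eggs, s["k_l"])
            r_next = spatial.beverton_holt(settled, p.h, p.R0, s["e0"])

            moved_state = PopState(
                B=b_moved, B_prev=state.B_prev, R=state.R,
                R_next=r_next, s_prev=state.s_prev,
            )
            b_next = popdyn.step_biomass(moved_state, p, s_now)
            if not np.all(np.isfinite(b_next)):
                bad = int(np.argmin(np.isfinite(b_next)))
                raise RuntimeError(
                    f"non-finite biomass for {p.name!r} in year {year}, patch {bad}"
                )

            a = audit[p.name]
            a["growth"][idx] = (1.0 + p.rho) * s_now * b_moved
            a["lag"][idx] = -p.rho * s_now * state.s_prev * state.B_prev
            a["recruit_drag"][idx] = -p.rho * s_now * p.w_km1 * state.R
            a["recruit_add"][idx] = p.w_k * r_next
            a["b_next"][idx] = b_next

            biomass[p.name][idx] = b_moved
            catches[p.name][idx] = c
            if p.role == "fished":
                fv_year += economics.fishery_profit(c, u, p.price, econ)
            if p.role == "tourism":
                b_res += float(b_moved[reserve_mask].sum())

            # rotate the lags
            s["state"] = PopState(
                B=b_next, B_prev=b_moved, R=r_next,
                R_next=r_next, s_prev=np.asarray(s_now, dtype=float),
            )

        fv[idx] = fv_year
        reserve_b[idx] = b_res

        if post and year in events_by_year and tourism is not None:
            ev = events_by_year[year]
            cap = economics.dives_demanded(ev.fee, b_res, tourism)
            tourism = replace(
                tourism, fee_policy="capped", fixed_fee=ev.fee, cap=cap
            )
            events_fired.append(
                f"year {year}: cap_dives at fee {ev.fee} -> cap {cap:.1f}"
            )

        if tourism is not None:
            fee_series[idx], dives[idx], tr[idx], cs[idx] = _annual_economics(
                tourism, b_res
            )
        else:
            fee_series[idx] = dives[idx] = tr[idx] = cs[idx] = 0.0

    return ScenarioResult(
        years=years, fv=fv, dives=dives, fee=fee_series, tr=tr, cs=cs,
        coast=coast, biomass=biomass, catch=catches, reserve_biomass=reserve_b,
        tourism_final=tourism, events_fired=events_fired, audit=audit,
    )


def payback_year(result: ScenarioResult) -> int | None:
    """First post-reserve year whose total value reaches the pre-reserve
    baseline (mean total value over the final 10 burn-in years); None if the
    baseline is never reached within the horizon."""
    tv = result.tv
    pre = result.years < 0
    baseline = float(tv[pre][-10:].mean())
    post_idx = np.flatnonzero(result.years >= 0)
    for i in post_idx:
        if tv[i] >= baseline:
            return int(result.years[i])
    return None
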