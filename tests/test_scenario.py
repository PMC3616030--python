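"""Scenario engine: zoning, reserve harvest rules, the full simulation loop."""

import dataclasses

import numpy as np
import pytest

from reservesim.economics import TourismParams
from reservesim.io_cli import generate_synthetic_scenario, medes_config
from reservesim.popdyn import SpeciesParams
from reservesim.scenario import (
    ManagementEvent,
    ScenarioConfig,
    SpeciesSetup,
    apply_reserve,
    build_zones,
    payback_year,
    run_simulation,
)


def counts(coast):
    return {z: sum(1 for x in coast.zone if x == z)
            for z in ("no_take", "partial", "open")}


class TestBuildZones:
    def test_medes_zoning(self):
        coast = build_zones(100, (0.01, 0.12, 0.87))
        c = counts(coast)
        assert c == {"no_take": 1, "partial": 12, "open": 87}
        assert coast.zone[50] == "no_take"
        # six partial patches flanking each side of the no-take patch
        assert all(coast.zone[i] == "partial" for i in range(44, 50))
        assert all(coast.zone[i] == "partial" for i in range(51, 57))

    def test_all_open(self):
        coast = build_zones(100, (0.0, 0.0, 1.0))
        assert counts(coast)["open"] == 100

    @pytest.mark.parametrize("n", [10, 33, 100, 157])
    @pytest.mark.parametrize("fr", [(0.01, 0.12, 0.87), (0.3, 0.3, 0.4),
                                    (0.5, 0.0, 0.5), (0.07, 0.21, 0.72)])
    def test_counts_always_sum_to_n(self, n, fr):
        coast = build_zones(n, fr)
        assert sum(counts(coast).values()) == n

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            build_zones(100, (0.5, 0.5, 0.5))


class TestApplyReserve:
    def test_zone_harvest_rules(self):
        coast = build_zones(100, (0.01, 0.12, 0.87))
        u = apply_reserve(0.4, coast, partial_reduction=0.5)
        assert u[50] == 0.0
        assert u[45] == pytest.approx(0.2)
        assert u[0] == pytest.approx(0.4)

    def test_zero_harvest_stays_zero(self):
        coast = build_zones(50, (0.1, 0.2, 0.7))
        assert np.all(apply_reserve(0.0, coast) == 0.0)

    def test_full_reduction_makes_partial_no_take(self):
        coast = build_zones(50, (0.1, 0.2, 0.7))
        u = apply_reserve(0.3, coast, partial_reduction=1.0)
        assert np.all(u[coast.zone_mask("partial")] == 0.0)


def quiet_config(**kw) -> ScenarioConfig:
    sp = SpeciesParams(name="sp", s_nat=0.7, w_k=100.0, w_km1=0.0, rho=0.6,
                       R0=1e4, sigma_L=2.0, sigma_A=1.0, h=0.75,
                       price=0.01, role="fished")
    base = dict(
        species=(SpeciesSetup(params=sp, u_pre=0.0),),
        n_patches=30, fractions=(0.1, 0.2, 0.7),
        burn_in_years=20, post_years=20, tourism=None,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestRunSimulation:
    def test_no_fishing_no_tourism_is_inert(self):
        res = run_simulation(quiet_config(burn_in_years=40, post_years=40))
        assert np.all(res.fv == 0) and np.all(res.tr == 0) and np.all(res.tv == 0)
        # biomass settles to a stationary profile: last two years identical
        for b in res.biomass.values():
            assert np.allclose(b[-1], b[-2], rtol=1e-7)

    def test_record_count_and_identity(self):
        res = run_simulation(quiet_config(burn_in_years=7, post_years=9))
        assert len(res.years) == 16
        assert res.years[0] == -7 and res.years[-1] == 8
        assert np.allclose(res.tv, res.fv + res.tr + res.cs)

    def test_protection_rebuilds_no_take_biomass(self, medes_result):
        """Releasing fishing mortality lifts no-take biomass above its fished
        level within 20 years, for both species."""
        res = medes_result
        mask = res.coast.zone_mask("no_take")
        pre_idx = res.years == -1
        y20 = res.years == 20
        for name, b in res.biomass.items():
            assert b[y20][0][mask].sum() > b[pre_idx][0][mask].sum()

    def test_species_order_does_not_matter(self):
        cfg = medes_config(burn_in_years=30, post_years=30)
        flipped = dataclasses.replace(cfg, species=tuple(reversed(cfg.species)))
        a, b = run_simulation(cfg), run_simulation(flipped)
        assert np.allclose(a.tv, b.tv, rtol=1e-12)
        for name in a.biomass:
            assert np.allclose(a.biomass[name], b.biomass[name], rtol=1e-12)

    def test_audit_terms_reconstruct_biomass_update(self, medes_result):
        """The stored recursion terms sum to the recorded next-year biomass."""
        for name, a in medes_result.audit.items():
            total = a["growth"] + a["lag"] + a["recruit_drag"] + a["recruit_add"]
            recon = np.maximum(total, 0.0)
            assert np.allclose(recon, a["b_next"], rtol=1e-6, atol=1e-6)

    def test_counterfactual_spillover_benefit(self):
        """With tourism off and heavy overfishing, long-run post-reserve
        fishery profit exceeds the no-reserve counterfactual."""
        cfg = medes_config()
        cfg = dataclasses.replace(cfg, tourism=None, events=())
        with_reserve = run_simulation(cfg)
        no_reserve = run_simulation(
            dataclasses.replace(cfg, fractions=(0.0, 0.0, 1.0)))
        assert with_reserve.fv[-1] > no_reserve.fv[-1]

    def test_nonfinite_state_aborts_with_diagnostic(self):
        bad = quiet_config()
        huge = dataclasses.replace(
            bad.species[0].params, R0=1e300, w_k=1e300)
        with pytest.raises((RuntimeError, OverflowError, ValueError)):
            run_simulation(dataclasses.replace(
                bad, species=(SpeciesSetup(params=huge, u_pre=0.0),)))


class TestDiveCapEvent:
    def test_cap_fires_and_freezes_fee_revenue(self, medes_capped_result):
        res = medes_capped_result
        t = res.tourism_final
        assert t.fee_policy == "capped" and t.fixed_fee == 3.5
        after = res.years >= 8
        assert np.allclose(res.tr[after], 3.5 * t.cap, rtol=1e-12)
        assert len(res.events_fired) == 1

    def test_nonbinding_cap_leaves_series_unchanged(self):
        cfg = medes_config()
        res_free = run_simulation(cfg)
        big_cap = TourismParams(
            alpha=res_free.tourism_final.alpha, beta=res_free.tourism_final.beta,
            gamma=res_free.tourism_final.gamma, fee_policy="capped",
            fixed_fee=3.5, cap=1e9)
        res_cap = run_simulation(dataclasses.replace(cfg, tourism=big_cap))
        assert np.allclose(res_cap.dives, res_free.dives, rtol=1e-12)


class TestPaybackYear:
    def test_no_drop_pays_back_immediately(self):
        res = run_simulation(quiet_config())
        assert payback_year(res) == 0

    def test_monotone_crossing_found(self, medes_result):
        pb = payback_year(medes_result)
        baseline = medes_result.tv[medes_result.years < 0][-10:].mean()
        tv_at = medes_result.tv[medes_result.years == pb][0]
        before = medes_result.tv[(medes_result.years >= 0)
                                 & (medes_result.years < pb)]
        assert tv_at >= baseline and np.all(before < baseline)

    def test_never_recovering_returns_none(self):
        # fishery-only scenario where closing ground permanently cuts profit:
        # lightly fished stock gains nothing from protection
        cfg = medes_config()
        cfg = dataclasses.replace(cfg, tourism=None, events=())
        light = dataclasses.replace(cfg.species[0], u_pre=0.05)
        cfg = dataclasses.replace(
            cfg, species=(light, cfg.species[1]), fractions=(0.3, 0.0, 0.7),
            post_years=30)
        res = run_simulation(cfg)
        assert payback_year(res) is None


class TestSyntheticScenarios:
    def test_runs_end_to_end_without_violating_invariants(self):
        for seed in range(3):
            res = run_simulation(generate_synthetic_scenario(seed))
            for b in res.biomass.values():
                assert np.all(b >= 0) and np.all(np.isfinite(b))
            assert np.all(res.dives >= 0) and np.all(res.cs >= -1e-9)
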