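import numpy as np
import pytest
from helpers_oracles import toy_ctfba_grid, toy_ctfba_kkt, toy_max_growth_grid

from mcmm.community import AbundanceProfile, CommunityModel
from mcmm.ctfba import (
    SolverError,
    fit_community,
    flux_range_at_optimum,
    solve_max_growth,
    tradeoff_scan,
)
from mcmm.medium import DietDefinition, Medium
from mcmm.synthetic import ARCHETYPES, make_taxon_model


def random_community(rng):
    """A 2-4 taxon community on a random glucose/inulin medium."""
    names = list(ARCHETYPES)
    chosen = rng.choice(names, size=rng.integers(2, 5), replace=False)
    weights = rng.dirichlet(np.ones(len(chosen)))
    weights = np.clip(weights, 1e-3, None)
    weights /= weights.sum()
    profile = AbundanceProfile("rand", dict(zip(chosen, weights)))
    medium = Medium.from_diet(DietDefinition("rand", {
        "glucose": float(rng.uniform(2, 20)),
        "inulin": float(rng.uniform(0, 10)),
        "acetate": float(rng.uniform(0, 5)),
    }))
    library = [make_taxon_model(n) for n in chosen]
    return CommunityModel.build(profile, library, medium)


class TestToyOracle:
    def test_step1_matches_grid_oracle(self, two_taxon_community):
        mu_star, _ = solve_max_growth(two_taxon_community)
        assert mu_star == pytest.approx(3.0, rel=1e-6)
        assert mu_star == pytest.approx(toy_max_growth_grid(), rel=1e-3)

    @pytest.mark.parametrize("tf", [0.5, 0.7, 0.9])
    def test_step2_matches_kkt_and_grid(self, two_taxon_community, tf):
        res = two_taxon_community.fit(tradeoff=tf)
        kkt_a, kkt_b = toy_ctfba_kkt(tf)
        grid_a, grid_b = toy_ctfba_grid(tf)
        assert kkt_a == pytest.approx(grid_a, abs=2e-3)  # oracle cross-check
        assert kkt_b == pytest.approx(grid_b, abs=2e-3)
        assert res.taxon_growth["butyrogen"] == pytest.approx(kkt_a, rel=1e-4)
        assert res.taxon_growth["non_producer"] == pytest.approx(kkt_b, rel=1e-4)

    def test_tf_one_forces_step1_optimum(self, two_taxon_community):
        res = two_taxon_community.fit(tradeoff=1.0)
        assert res.community_growth == pytest.approx(3.0, abs=1e-6)

    def test_butyrate_production_forced_by_unique_qp(self, two_taxon_community):
        res = two_taxon_community.fit(tradeoff=0.7)
        # mu_A = 2.0 => glucose uptake 10 => 20 mmol butyrate/gDW_A/h, x0.5
        assert res.production_rates()["butyrate"] == pytest.approx(10.0,
                                                                   rel=1e-4)

    def test_glucose_net_import_floored_at_zero(self, two_taxon_community):
        res = two_taxon_community.fit(tradeoff=0.7)
        rates = res.production_rates()
        assert rates["glucose"] == 0.0
        assert "propionate" not in rates  # never exchanged by these taxa


def test_single_butyrogen_optimum(butyrogen, glucose_medium):
    cm = CommunityModel.build(
        AbundanceProfile("solo", {"butyrogen": 1.0}), [butyrogen],
        glucose_medium,
    )
    mu_star, _ = solve_max_growth(cm)
    assert mu_star == pytest.approx(2.0, rel=1e-6)


def test_empty_medium_zero_growth(butyrogen):
    empty = Medium.from_diet(DietDefinition("empty", {}))
    cm = CommunityModel.build(
        AbundanceProfile("solo", {"butyrogen": 1.0}), [butyrogen], empty
    )
    res = cm.fit(tradeoff=0.7)
    assert res.status == "optimal"
    assert res.max_community_growth == pytest.approx(0.0, abs=1e-9)
    assert all(mu == pytest.approx(0.0, abs=1e-9)
               for mu in res.taxon_growth.values())


def test_production_rates_require_optimal(two_taxon_community):
    res = two_taxon_community.fit(tradeoff=0.7)
    res.status = "infeasible"
    with pytest.raises(SolverError):
        res.production_rates()


class TestFluxRanges:
    def test_unique_pathway_width_zero(self, two_taxon_community):
        res = two_taxon_community.fit(tradeoff=0.7)
        lo, hi = flux_range_at_optimum(two_taxon_community, res, "butyrate")
        assert hi - lo == pytest.approx(0.0, abs=1e-4)

    def test_degenerate_split_width_positive(self, degenerate_community):
        res = degenerate_community.fit(tradeoff=0.7)
        lo_a, hi_a = res.flux_range("acetate")
        lo_p, hi_p = res.flux_range("propionate")
        assert hi_a - lo_a > 1.0
        assert hi_p - lo_p == pytest.approx(0.0, abs=1e-4)

    def test_fixing_growth_narrows_range(self, degenerate_community):
        """The mu-fixed range is nested in the range under the tradeoff
        constraint alone (feasible-set nesting)."""
        from scipy.optimize import linprog

        cm = degenerate_community
        res = cm.fit(tradeoff=0.7)
        lo, hi = res.flux_range("acetate")
        j = cm.community_ex_col["acetate"]
        wide = []
        for sign in (1.0, -1.0):
            c = np.zeros(cm.S.shape[1])
            c[j] = sign
            out = linprog(
                c, A_ub=-cm.objective[None, :],
                b_ub=[-0.7 * res.max_community_growth],
                A_eq=cm.S, b_eq=np.zeros(cm.S.shape[0]),
                bounds=list(zip(cm.lb, cm.ub)), method="highs",
            )
            wide.append(sign * out.fun)
        assert wide[0] - 1e-6 <= lo and hi <= wide[1] + 1e-6


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_communities(self, seed):
        rng = np.random.default_rng(seed)
        cm = random_community(rng)
        res = cm.fit(tradeoff=0.7)
        assert res.status == "optimal"
        assert res.steady_state_violation <= 1e-6
        assert res.community_growth >= 0.7 * res.max_community_growth - 1e-6
        mu_sum = sum(a * res.taxon_growth[m.taxon_id] for m, a in cm.members)
        assert res.community_growth == pytest.approx(mu_sum, abs=1e-6)

    def test_growth_norm_monotone_in_tradeoff(self, two_taxon_community):
        norms = []
        for tf in (0.3, 0.5, 0.7, 0.9, 1.0):
            res = two_taxon_community.fit(tradeoff=tf)
            norms.append(sum(mu**2 for mu in res.taxon_growth.values()))
        assert all(a <= b + 1e-6 for a, b in zip(norms, norms[1:]))

    def test_relaxing_medium_never_decreases_optimum(self, toy_library):
        profile = AbundanceProfile("s", {"butyrogen": 0.5, "non_producer": 0.5})
        mus = []
        for bound in (2.0, 5.0, 10.0, 50.0):
            medium = Medium.from_diet(DietDefinition("d", {"glucose": bound}))
            cm = CommunityModel.build(profile, toy_library, medium)
            mus.append(solve_max_growth(cm)[0])
        assert all(a <= b + 1e-9 for a, b in zip(mus, mus[1:]))


def test_tradeoff_scan_reports_growing_fraction(two_taxon_community):
    scan = tradeoff_scan(two_taxon_community, tradeoffs=[0.3, 0.7, 1.0])
    assert list(scan["tradeoff"]) == [0.3, 0.7, 1.0]
    assert (scan["status"] == "optimal").all()
    # both taxa grow at every tradeoff in this toy
    assert (scan["fraction_growing"] == 1.0).all()


def test_summary_renders(two_taxon_community):
    res = two_taxon_community.fit(tradeoff=0.7)
    text = res.summary()
    assert "butyrogen" in text and "tradeoff" in text
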