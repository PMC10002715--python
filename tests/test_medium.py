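import pytest

from mcmm.gem_core import fba_optimum
from mcmm.medium import (
    CompletionInfeasibleError,
    DietDefinition,
    Medium,
    add_host_metabolites,
    apply_host_absorption,
    assert_growth_floor,
    build_medium,
    complete_medium,
    dilute,
    read_diet_tsv,
    replay,
    strip_carbon,
    supplement_fiber,
    write_diet_tsv,
)
from mcmm.synthetic import TaxonArchetype, default_diet, make_taxon_model


@pytest.fixture
def diet():
    return DietDefinition(
        "toy_diet",
        {"glucose": 10.0, "starch": 1.0, "fe3": 0.1},
        flags={
            "glucose": {"host_absorbable": True},
            "starch": {"residual_fiber": True},
        },
        formulas={"glucose": "C6H12O6", "starch": "C18H32O16", "fe3": "Fe"},
    )


@pytest.fixture
def iron_butyrogen():
    arch = TaxonArchetype("iron_butyrogen", "glucose", 0.2, {"butyrate": 2.0},
                          extra_requirements={"fe3": 0.01})
    return make_taxon_model(arch)


class TestHostAbsorption:
    def test_absorbable_diluted_to_20_percent(self, diet):
        medium = apply_host_absorption(diet)
        assert medium.entries["glucose"] == pytest.approx(2.0)

    def test_unflagged_unchanged(self, diet):
        medium = apply_host_absorption(diet)
        assert medium.entries["starch"] == 1.0
        assert medium.entries["fe3"] == 0.1

    def test_retain_one_is_identity(self, diet):
        medium = apply_host_absorption(diet, retain=1.0)
        assert medium.entries == diet.entries


class TestHostMetabolites:
    def test_new_entry_added_with_flag(self, diet):
        medium = add_host_metabolites(apply_host_absorption(diet), {"mucin": 1.0})
        assert medium.entries["mucin"] == 1.0
        assert medium.flag("mucin", "host_supplied")

    def test_merge_keeps_max(self, diet):
        medium = Medium.from_diet(diet)
        medium.entries["mucin"] = 2.0
        out = add_host_metabolites(medium, {"mucin": 1.0})
        assert out.entries["mucin"] == 2.0

    def test_empty_set_is_identity(self, diet):
        medium = Medium.from_diet(diet)
        assert add_host_metabolites(medium, {}).entries == medium.entries


class TestCompletion:
    def test_adds_only_missing_iron(self, iron_butyrogen):
        medium = Medium.from_diet(DietDefinition("dm", {"glucose": 10.0}))
        completed, additions = complete_medium(medium, [iron_butyrogen],
                                               growth_floor=0.3)
        # floor 0.3 => catabolic flux 1.5 => 0.015 mmol/gDW/h of iron
        assert set(additions) == {"fe3"}
        assert additions["fe3"] == pytest.approx(0.015, rel=1e-6)
        assert fba_optimum(iron_butyrogen, completed.entries) >= 0.3 - 1e-9

    def test_already_complete_adds_nothing(self, iron_butyrogen):
        medium = Medium.from_diet(
            DietDefinition("dm", {"glucose": 10.0, "fe3": 1.0})
        )
        completed, additions = complete_medium(medium, [iron_butyrogen])
        assert additions == {}
        assert completed.entries == medium.entries

    def test_idempotent(self, iron_butyrogen):
        medium = Medium.from_diet(DietDefinition("dm", {"glucose": 10.0}))
        once, _ = complete_medium(medium, [iron_butyrogen])
        twice, additions = complete_medium(once, [iron_butyrogen])
        assert additions == {} and twice.entries == once.entries

    def test_infeasible_when_requirement_not_a_candidate(self, iron_butyrogen):
        medium = Medium.from_diet(DietDefinition("dm", {}))
        with pytest.raises(CompletionInfeasibleError, match="iron_butyrogen"):
            complete_medium(medium, [iron_butyrogen],
                            candidates={"glucose"})  # iron not offered


class TestStripCarbon:
    def test_rule_application(self, diet):
        medium = strip_carbon(Medium.from_diet(diet))
        assert set(medium.entries) == {"starch", "fe3"}

    def test_no_carbon_is_identity(self):
        medium = Medium.from_diet(
            DietDefinition("m", {"fe3": 0.1}, formulas={"fe3": "Fe"})
        )
        assert strip_carbon(medium).entries == medium.entries

    def test_host_supplied_carbon_retained(self, diet):
        medium = add_host_metabolites(
            Medium.from_diet(diet), {"mucin": 1.0},
            formulas={"mucin": "C30H50N2O20"},
        )
        stripped = strip_carbon(medium)
        assert stripped.entries["mucin"] == 1.0

    def test_override_flag_marks_formula_free_carbon_source(self):
        diet = DietDefinition(
            "m", {"mystery": 1.0},
            flags={"mystery": {"carbon_source_override": True}},
        )
        assert strip_carbon(Medium.from_diet(diet)).entries == {}


class TestDilute:
    def test_ten_percent(self, diet):
        medium = dilute(Medium.from_diet(diet), 0.1)
        assert medium.entries["glucose"] == pytest.approx(1.0)

    def test_residual_fiber_scaled_to_study_dilution(self, diet):
        medium = dilute(Medium.from_diet(diet), 0.1, fiber_dilution=5)
        assert medium.entries["starch"] == pytest.approx(1.0 / 5)
        assert medium.entries["glucose"] == pytest.approx(1.0)

    def test_identity_case(self, diet):
        medium = dilute(Medium.from_diet(diet), 1.0)
        assert medium.entries == diet.entries

    def test_bad_fiber_dilution(self, diet):
        with pytest.raises(ValueError):
            dilute(Medium.from_diet(diet), 0.1, fiber_dilution=-1)


@pytest.mark.parametrize(
    "fiber, expected", [("pectin", 1.0), ("inulin", 10.0), ("fos", 100.0)]
)
def test_fiber_supplement_defaults(diet, fiber, expected):
    medium = supplement_fiber(Medium.from_diet(diet), fiber)
    assert medium.entries[fiber] == expected


def test_unknown_fiber_rejected(diet):
    with pytest.raises(ValueError, match="unknown fiber"):
        supplement_fiber(Medium.from_diet(diet), "cellulose")


class TestBuildMedium:
    def test_ex_vivo_carbon_only_in_fiber_and_host(self, diet, iron_butyrogen):
        medium = build_medium(
            diet, "ex_vivo", models=[iron_butyrogen],
            host_metabolites={"mucin": 1.0},
            host_formulas={"mucin": "C30H50N2O20"},
            fiber_dilution=5,
        )
        for m in medium.entries:
            if medium.carbon(m) > 0:
                assert medium.flag(m, "residual_fiber") or medium.flag(
                    m, "host_supplied"
                )

    def test_in_vivo_keeps_absorbable_carbon_at_20_percent(self, diet):
        medium = build_medium(diet, "in_vivo")
        assert medium.entries["glucose"] == pytest.approx(0.2 * 10.0)

    def test_ex_vivo_requires_fiber_dilution(self, diet):
        with pytest.raises(ValueError, match="fiber_dilution"):
            build_medium(diet, "ex_vivo")

    def test_growth_floor_holds_pre_strip(self, iron_butyrogen):
        medium = build_medium(default_diet(), "in_vivo",
                              models=[iron_butyrogen], growth_floor=0.3)
        assert_growth_floor(medium, [iron_butyrogen], 0.3)


class TestProvenanceReplay:
    def test_replay_reproduces_medium_bit_exactly(self, diet, iron_butyrogen):
        medium = build_medium(
            diet, "ex_vivo", models=[iron_butyrogen],
            host_metabolites={"mucin": 1.0},
            host_formulas={"mucin": "C30H50N2O20"},
            fiber_dilution=5, supplement="inulin",
        )
        again = replay(diet, medium.history)
        assert again.entries == medium.entries
        assert again.provenance == medium.provenance

    def test_transforms_monotone(self, diet):
        """Absorption, stripping, dilution never increase any entry."""
        m0 = Medium.from_diet(diet)
        for transform in (
            lambda m: apply_host_absorption(m, 0.2),
            strip_carbon,
            lambda m: dilute(m, 0.1, 5),
        ):
            m1 = transform(m0)
            for met, flux in m1.entries.items():
                assert flux <= m0.entries[met] + 1e-12


def test_diet_tsv_round_trip(tmp_path, diet):
    path = tmp_path / "diet.tsv"
    write_diet_tsv(diet, path)
    loaded = read_diet_tsv(path)
    assert loaded.entries == diet.entries
    assert loaded.formulas == diet.formulas
    for m in diet.entries:
        for flag in ("host_absorbable", "residual_fiber"):
            assert loaded.flag(m, flag) == diet.flag(m, flag)
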