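import pytest

from gemtx import (
    MappingScheme,
    MediumComposition,
    ThresholdConfig,
    ThresholdSpec,
    TranscriptomeDataset,
    ValidationError,
    apply_medium,
    build_context_model,
    classify,
    fba,
    map_reaction_expression,
)


def make_classification(dataset, threshold=10.0):
    return classify(dataset, ThresholdConfig("GT1", ThresholdSpec("exact", threshold)))


class TestApplyMedium:
    def test_listed_bounds_applied_and_audited(self, chain_model):
        medium = MediumComposition(bounds={"EX_S": (-5.0, 0.0)})
        ctx = apply_medium(chain_model, medium)
        assert ctx.model.reaction("EX_S").lower_bound == -5.0
        assert len(ctx.audit) == 1
        assert ctx.audit[0].cause == "medium"

    def test_close_unlisted_shuts_uptakes(self, chain_model):
        from gemtx import Reaction

        chain_model.metabolites.append("X")
        chain_model.reactions.append(Reaction("EX_X", -5.0, 5.0))
        chain_model.stoichiometry[("X", "EX_X")] = -1.0
        chain_model.validate()
        ctx = apply_medium(chain_model, MediumComposition(bounds={"EX_S": (-10.0, 0.0)}),
                           close_unlisted=True)
        assert ctx.model.reaction("EX_X").lower_bound == 0.0
        assert ctx.model.reaction("EX_X").upper_bound == 5.0  # secretion stays open

    def test_empty_medium_is_identity(self, chain_model):
        ctx = apply_medium(chain_model, MediumComposition())
        assert ctx.audit == []
        for rxn in chain_model.reactions:
            copy = ctx.model.reaction(rxn.id)
            assert (copy.lower_bound, copy.upper_bound) == (rxn.lower_bound, rxn.upper_bound)

    def test_unknown_reaction_rejected(self, chain_model):
        with pytest.raises(ValidationError, match="EX_missing"):
            apply_medium(chain_model, MediumComposition(bounds={"EX_missing": (-1.0, 0.0)}))


class TestMapReactionExpression:
    def test_or_takes_max(self, isozyme_model):
        ds = TranscriptomeDataset("WT", "S1", {"gA": 100.0, "gB": 50.0})
        mapped = map_reaction_expression(isozyme_model, ds)
        assert mapped["R1"] == 100.0

    def test_empty_gpr_is_undefined(self, isozyme_model):
        ds = TranscriptomeDataset("WT", "S1", {"gA": 100.0})
        mapped = map_reaction_expression(isozyme_model, ds)
        assert mapped["EX_S"] is None
        assert mapped["BIOMASS"] is None

    def test_missing_operand_skipped(self, isozyme_model):
        ds = TranscriptomeDataset("WT", "S1", {"gC": 100.0})
        mapped = map_reaction_expression(isozyme_model, ds)  # gpr "gC and gD", gD unmeasured
        assert mapped["R2"] == 100.0


class TestConstrainingOptions:
    def test_irreversible_only_caps_forward_bound(self, isozyme_model):
        ds = TranscriptomeDataset("WT", "S1", {"g3": 5.0})
        ctx = build_context_model(
            isozyme_model, ds, make_classification(ds), option="IRREVERSIBLE_ONLY"
        )
        assert ctx.model.reaction("R3").upper_bound == 5.0

    def test_irreversible_only_leaves_reversible_untouched(self, reversible_model):
        ds = TranscriptomeDataset("WT", "S1", {"gX": 7.0})
        ctx = build_context_model(
            reversible_model, ds, make_classification(ds), option="IRREVERSIBLE_ONLY"
        )
        rxn = ctx.model.reaction("R_REV")
        assert (rxn.lower_bound, rxn.upper_bound) == (-1000.0, 1000.0)

    def test_all_reactions_caps_reversible_both_ways(self, reversible_model):
        ds = TranscriptomeDataset("WT", "S1", {"gX": 7.0})
        ctx = build_context_model(
            reversible_model, ds, make_classification(ds), option="ALL_REACTIONS"
        )
        rxn = ctx.model.reaction("R_REV")
        assert (rxn.lower_bound, rxn.upper_bound) == (-7.0, 7.0)

    def test_backward_irreversible_capped_in_its_direction(self, reversible_model):
        ds = TranscriptomeDataset("WT", "S1", {"gY": 6.0})
        ctx = build_context_model(
            reversible_model, ds, make_classification(ds), option="IRREVERSIBLE_ONLY"
        )
        rxn = ctx.model.reaction("R_BACK")
        assert (rxn.lower_bound, rxn.upper_bound) == (-6.0, 0.0)

    def test_nonessential_deletion_spares_essential_gene(self, isozyme_model):
        # every measured gene is below threshold; g3 sits on the only route
        ds = TranscriptomeDataset(
            "WT", "S1", {"gA": 2.0, "gB": 1.0, "gC": 500.0, "gD": 400.0, "g3": 1.0}
        )
        ctx = build_context_model(
            isozyme_model, ds, make_classification(ds, threshold=10.0),
            option="NONESSENTIAL_DELETION",
        )
        assert "g3" not in ctx.deleted_genes
        skipped = {e.reaction for e in ctx.audit if e.cause == "skipped_essential"}
        assert "g3" in skipped

    def test_nonessential_deletion_removes_redundant_isozyme(self, isozyme_model):
        ds = TranscriptomeDataset(
            "WT", "S1", {"gA": 2.0, "gB": 100.0, "gC": 500.0, "gD": 400.0, "g3": 50.0}
        )
        ctx = build_context_model(
            isozyme_model, ds, make_classification(ds, threshold=10.0),
            option="NONESSENTIAL_DELETION",
        )
        assert ctx.deleted_genes == ["gA"]
        # R1 keeps its isozyme twin, so no reaction is blocked
        assert not [e for e in ctx.audit if e.cause == "gene_deletion"]

    def test_deleting_both_isozymes_blocks_reaction(self, isozyme_model):
        # both isozymes suppressed and individually neutral -> joint deletion
        # blocks R1; that is the documented single-deletion semantics
        ds = TranscriptomeDataset(
            "WT", "S1", {"gA": 2.0, "gB": 3.0, "gC": 500.0, "gD": 400.0, "g3": 50.0}
        )
        ctx = build_context_model(
            isozyme_model, ds, make_classification(ds, threshold=10.0),
            option="NONESSENTIAL_DELETION",
        )
        assert set(ctx.deleted_genes) == {"gA", "gB"}
        blocked = [e for e in ctx.audit if e.cause == "gene_deletion"]
        assert [e.reaction for e in blocked] == ["R1"]
        assert ctx.model.reaction("R1").upper_bound == 0.0

    def test_meet_min_growth_skips_starving_caps(self, isozyme_model):
        # unique route needs 10 units of flux everywhere; a mapped value of 4
        # on R3 would starve it, so the cap must be skipped and audited
        ds = TranscriptomeDataset(
            "WT", "S1", {"gA": 100.0, "gB": 90.0, "gC": 80.0, "gD": 70.0, "g3": 4.0}
        )
        ctx = build_context_model(
            isozyme_model, ds, make_classification(ds, threshold=10.0),
            option="MEET_MIN_GROWTH",
        )
        assert ctx.model.reaction("R3").upper_bound == 1000.0
        skipped = {e.reaction for e in ctx.audit if e.cause == "skipped_min_growth"}
        assert skipped == {"R3"}
        # caps at or above the requirement are still applied
        assert ctx.model.reaction("R2").upper_bound == 70.0

    def test_meet_min_growth_preserves_optimum(self, isozyme_model):
        ds = TranscriptomeDataset(
            "WT", "S1", {"gA": 100.0, "gB": 90.0, "gC": 80.0, "gD": 70.0, "g3": 4.0}
        )
        ctx = build_context_model(
            isozyme_model, ds, make_classification(ds, threshold=10.0),
            option="MEET_MIN_GROWTH",
        )
        assert fba(ctx).objective_value == pytest.approx(10.0, abs=1e-6)


class TestInvariants:
    @pytest.fixture
    def any_context(self, isozyme_model):
        ds = TranscriptomeDataset(
            "WT", "S1", {"gA": 2.0, "gB": 8.0, "gC": 500.0, "gD": 4.0, "g3": 6.0}
        )
        classification = make_classification(ds, threshold=5.0)
        return isozyme_model, ds, classification

    @pytest.mark.parametrize(
        "option", ["IRREVERSIBLE_ONLY", "ALL_REACTIONS", "NONESSENTIAL_DELETION", "MEET_MIN_GROWTH"]
    )
    def test_expression_bounds_never_widen(self, any_context, option):
        model, ds, classification = any_context
        ctx = build_context_model(model, ds, classification, option=option)
        for entry in ctx.audit:
            if entry.cause == "expression_bound":
                assert entry.new_lb >= entry.old_lb
                assert entry.new_ub <= entry.old_ub

    @pytest.mark.parametrize(
        "option", ["IRREVERSIBLE_ONLY", "ALL_REACTIONS", "NONESSENTIAL_DELETION", "MEET_MIN_GROWTH"]
    )
    def test_constraining_never_raises_optimum(self, any_context, option):
        model, ds, classification = any_context
        source_optimum = fba(model).objective_value
        ctx = build_context_model(model, ds, classification, option=option)
        assert fba(ctx).objective_value <= source_optimum + 1e-6

    def test_neutral_deletions_preserve_growth(self, isozyme_model):
        """With only a grRatio==1 gene deleted and generous caps, growth is unchanged."""
        ds = TranscriptomeDataset(
            "WT", "S1", {"gA": 2.0, "gB": 900.0, "gC": 800.0, "gD": 700.0, "g3": 600.0}
        )
        ctx = build_context_model(
            isozyme_model, ds, make_classification(ds, threshold=10.0),
            option="NONESSENTIAL_DELETION",
        )
        assert ctx.deleted_genes == ["gA"]
        assert fba(ctx).objective_value == pytest.approx(fba(isozyme_model).objective_value, abs=1e-6)

    @pytest.mark.parametrize(
        "option", ["IRREVERSIBLE_ONLY", "ALL_REACTIONS", "NONESSENTIAL_DELETION", "MEET_MIN_GROWTH"]
    )
    def test_idempotent_under_identical_inputs(self, any_context, option):
        model, ds, classification = any_context
        first = build_context_model(model, ds, classification, option=option)
        second = build_context_model(model, ds, classification, option=option)
        bounds = lambda ctx: [(r.id, r.lower_bound, r.upper_bound) for r in ctx.model.reactions]
        assert bounds(first) == bounds(second)
        assert first.deleted_genes == second.deleted_genes
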