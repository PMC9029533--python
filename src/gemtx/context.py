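"""Context-specific model construction.

Medium bounds and expression-derived constraints are applied to a copy of the
source model, with every bound change recorded in an audit trail.  Mapped
expression values act as magnitude caps on flux (E-Flux style): an
irreversible reaction's upper bound is capped at the mapped value, a backward
irreversible reaction's lower bound at its negation, and (under the
all-reactions option) a reversible reaction is capped in both directions.
Bounds only ever tighten; a cap above the existing bound changes nothing.

Four constraining options are supported: cap only (backward) irreversible
reactions; cap all reactions; delete suppressed genes whose knockout provably
does not affect growth (single-gene-deletion growth ratio equal to 1) before
capping; or cap only where the mapped value still permits the reaction's
minimum flux requirement at optimal growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import pandas as pd

from .errors import InfeasibleContextError, ValidationError
from .gpr import MappingScheme, evaluate_gpr, parse_gpr
from .model_io import MediumComposition, MetabolicModel, TranscriptomeDataset
from .optimize import FLUX_EPS, apply_gene_knockout, fba, min_growth_requirements, single_gene_deletion
from .thresholding import GeneClassification

__all__ = [
    "AuditEntry",
    "ContextModel",
    "apply_medium",
    "map_reaction_expression",
    "build_context_model",
    "CONSTRAIN_OPTIONS",
]

CONSTRAIN_OPTIONS = (
    "IRREVERSIBLE_ONLY",
    "ALL_REACTIONS",
    "NONESSENTIAL_DELETION",
    "MEET_MIN_GROWTH",
)

GR_RATIO_TOL = 1e-6  # |grRatio - 1| below this counts as growth-neutral


@dataclass(frozen=True)
class AuditEntry:
    """One recorded decision; for gene-level causes ``reaction`` holds the gene id
    and the bounds are unchanged."""

    reaction: str
    old_lb: float
    old_ub: float
    new_lb: float
    new_ub: float
    cause: Literal[
        "medium", "expression_bound", "gene_deletion", "skipped_min_growth", "skipped_essential"
    ]


@dataclass
class ContextModel:
    """A mutated model copy plus the audit trail that produced it."""

    model: MetabolicModel
    audit: list[AuditEntry] = field(default_factory=list)
    deleted_genes: list[str] = field(default_factory=list)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.reaction, e.old_lb, e.old_ub, e.new_lb, e.new_ub, e.cause)
                for e in self.audit
            ],
            columns=["reaction", "old_lb", "old_ub", "new_lb", "new_ub", "cause"],
        )

    def expression_constrained_reactions(self) -> set[str]:
        """Reactions whose bounds were tightened because of the transcriptome."""
        return {
            e.reaction
            for e in self.audit
            if e.cause in ("expression_bound", "gene_deletion")
        }

    def expression_bounds(self) -> dict[str, AuditEntry]:
        return {e.reaction: e for e in self.audit if e.cause == "expression_bound"}


def apply_medium(
    model: MetabolicModel,
    medium: Optional[MediumComposition],
    close_unlisted: bool = False,
) -> ContextModel:
    """Set the medium file's bounds on its exchange reactions.

    With ``close_unlisted`` every exchange reaction absent from the medium has
    its uptake (negative lower bound) closed, so the model can consume only
    what the medium provides.
    """
    ctx = ContextModel(model=model.copy())
    if medium is None:
        medium = MediumComposition()
    known = set(ctx.model.reaction_ids)
    unknown = sorted(set(medium.bounds) - known)
    if unknown:
        raise ValidationError("medium lists unknown reactions: " + ", ".join(unknown))
    for rxn_id, (lb, ub) in medium.bounds.items():
        rxn = ctx.model.reaction(rxn_id)
        if (rxn.lower_bound, rxn.upper_bound) != (lb, ub):
            ctx.audit.append(
                AuditEntry(rxn_id, rxn.lower_bound, rxn.upper_bound, lb, ub, "medium")
            )
            rxn.lower_bound, rxn.upper_bound = lb, ub
    if close_unlisted:
        for rxn_id in ctx.model.exchange_reactions():
            if rxn_id in medium.bounds:
                continue
            rxn = ctx.model.reaction(rxn_id)
            if rxn.lower_bound < 0:
                ctx.audit.append(
                    AuditEntry(rxn_id, rxn.lower_bound, rxn.upper_bound, 0.0, rxn.upper_bound, "medium")
                )
                rxn.lower_bound = 0.0
    return ctx


def map_reaction_expression(
    model: MetabolicModel,
    dataset: TranscriptomeDataset,
    scheme: MappingScheme = MappingScheme(),
    missing_policy: str = "skip",
) -> dict[str, Optional[float]]:
    """Evaluate every reaction's GPR against a sample's expression values.

    Reactions with an empty GPR map to ``None`` (undefined) and are never
    constrained by expression.
    """
    mapped: dict[str, Optional[float]] = {}
    for rxn in model.reactions:
        try:
            expr = parse_gpr(rxn.gpr)
        except Exception as exc:
            raise ValidationError(f"reaction {rxn.id!r}: bad GPR: {exc}") from exc
        mapped[rxn.id] = evaluate_gpr(expr, dataset.expression, scheme, missing_policy)
    return mapped


def _cap_reaction(ctx: ContextModel, rxn_id: str, value: float, include_reversible: bool) -> None:
    rxn = ctx.model.reaction(rxn_id)
    old = (rxn.lower_bound, rxn.upper_bound)
    direction = rxn.direction
    if direction == "irreversible":
        new = (old[0], min(old[1], value))
    elif direction == "backward_irreversible":
        new = (max(old[0], -value), old[1])
    else:
        if not include_reversible:
            return
        new = (max(old[0], -value), min(old[1], value))
    if new != old:
        ctx.audit.append(AuditEntry(rxn_id, old[0], old[1], new[0], new[1], "expression_bound"))
        rxn.lower_bound, rxn.upper_bound = new


def _delete_nonessential(
    ctx: ContextModel, base: MetabolicModel, classification: GeneClassification
) -> None:
    """Delete suppressed genes whose single knockout leaves growth unchanged
    (grRatio == 1 against the medium-constrained wild type)."""
    model_genes = set(base.genes)
    for gene in sorted(classification.suppressed_genes()):
        if gene not in model_genes:
            continue
        ratio = single_gene_deletion(base, gene)
        if abs(ratio - 1.0) <= GR_RATIO_TOL:
            ctx.deleted_genes.append(gene)
        else:
            ctx.audit.append(AuditEntry(gene, 0.0, 0.0, 0.0, 0.0, "skipped_essential"))
    if ctx.deleted_genes:
        knocked, blocked = apply_gene_knockout(ctx.model, set(ctx.deleted_genes))
        for rxn_id in blocked:
            rxn = ctx.model.reaction(rxn_id)
            if (rxn.lower_bound, rxn.upper_bound) != (0.0, 0.0):
                ctx.audit.append(
                    AuditEntry(rxn_id, rxn.lower_bound, rxn.upper_bound, 0.0, 0.0, "gene_deletion")
                )
                rxn.lower_bound, rxn.upper_bound = 0.0, 0.0


def build_context_model(
    model: MetabolicModel,
    dataset: TranscriptomeDataset,
    classification: Optional[GeneClassification],
    scheme: MappingScheme = MappingScheme(),
    option: str = "ALL_REACTIONS",
    medium: Optional[MediumComposition] = None,
    close_unlisted: bool = False,
    missing_policy: str = "skip",
    scale: float = 1.0,
) -> ContextModel:
    """Build a context-specific model under one of the four constraining options.

    ``scale`` linearly rescales mapped expression values before they are used
    as flux caps (default 1.0: values used verbatim).  ``classification`` is
    required for the deletion-based options, which knock out suppressed genes.
    """
    if option not in CONSTRAIN_OPTIONS:
        raise ValidationError(f"unknown constraining option {option!r}")
    if option in ("NONESSENTIAL_DELETION", "MEET_MIN_GROWTH") and classification is None:
        raise ValidationError(f"{option} requires a gene classification")

    ctx = apply_medium(model, medium, close_unlisted)
    mapped = map_reaction_expression(model, dataset, scheme, missing_policy)
    if scale != 1.0:
        mapped = {r: (None if v is None else v * scale) for r, v in mapped.items()}

    if option == "IRREVERSIBLE_ONLY":
        for rxn_id, value in mapped.items():
            if value is not None:
                _cap_reaction(ctx, rxn_id, value, include_reversible=False)
        return ctx

    if option == "ALL_REACTIONS":
        for rxn_id, value in mapped.items():
            if value is not None:
                _cap_reaction(ctx, rxn_id, value, include_reversible=True)
        return ctx

    # deletion-based options share the medium-constrained wild type as the
    # grRatio baseline
    base = ctx.model.copy()

    if option == "NONESSENTIAL_DELETION":
        _delete_nonessential(ctx, base, classification)
        blocked = {
            e.reaction for e in ctx.audit if e.cause == "gene_deletion"
        }
        for rxn_id, value in mapped.items():
            if value is not None and rxn_id not in blocked:
                _cap_reaction(ctx, rxn_id, value, include_reversible=True)
        return ctx

    # MEET_MIN_GROWTH: an auxiliary model with only medium + deletions applied
    # supplies each reaction's minimum flux requirement at optimal growth.
    _delete_nonessential(ctx, base, classification)
    aux = ContextModel(model=ctx.model.copy())
    aux_solution = fba(aux)
    if aux_solution.status != "optimal":
        raise InfeasibleContextError(
            "auxiliary model (medium + gene deletions only) is infeasible",
            active_constraints=[
                f"{e.reaction}: [{e.new_lb}, {e.new_ub}] ({e.cause})" for e in ctx.audit
            ],
        )
    requirements = min_growth_requirements(aux)
    blocked = {e.reaction for e in ctx.audit if e.cause == "gene_deletion"}
    for rxn_id, value in mapped.items():
        if value is None or rxn_id in blocked:
            continue
        needed = requirements.get(rxn_id, 0.0)
        if value + FLUX_EPS < needed:
            rxn = ctx.model.reaction(rxn_id)
            ctx.audit.append(
                AuditEntry(
                    rxn_id, rxn.lower_bound, rxn.upper_bound,
                    rxn.lower_bound, rxn.upper_bound, "skipped_min_growth",
                )
            )
        else:
            _cap_reaction(ctx, rxn_id, value, include_reversible=True)
    return ctx
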