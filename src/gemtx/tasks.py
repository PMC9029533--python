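"""User-facing analyses.

Non-optimization tasks work on gene classifications alone: splitting genes
into high-/low-expression lists and comparing expression between phenotypes.
Post-optimization tasks interrogate a context-specific model through FVA:
reactions silenced by the transcriptome (non-flux), reactions whose
expression-derived cap binds the flux (rate-limiting), and FVA flux-range
shifts between phenotypes.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .context import ContextModel
from .errors import ValidationError
from .model_io import TranscriptomeDataset
from .optimize import FLUX_EPS, FvaResult
from .thresholding import EXPRESSED, GeneClassification

__all__ = [
    "filter_high_low",
    "filter_low",
    "compare_expression",
    "non_flux_reactions",
    "rate_limiting_reactions",
    "flux_shifts",
]

RATIO_TOL = 1e-6  # relative tolerance for "unchanged" calls on ratios

UP, DOWN, UNCHANGED, NEW, LOST = "up", "down", "unchanged", "new", "lost"


def _classification_frame(classification: GeneClassification) -> pd.DataFrame:
    genes = sorted(classification.status)
    return pd.DataFrame(
        {
            "gene": genes,
            "value": [classification.values.get(g, float("nan")) for g in genes],
            "status": [classification.status[g] for g in genes],
            "deciding_threshold": [classification.applied[g] for g in genes],
        }
    )


def filter_high_low(
    classification: GeneClassification,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one sample's genes into high- and low-expression tables.

    Both frames carry gene, value, status and the threshold that decided the
    call; together they partition the sample's genes.
    """
    frame = _classification_frame(classification)
    high = frame[frame["status"] == EXPRESSED].reset_index(drop=True)
    low = frame[frame["status"] != EXPRESSED].reset_index(drop=True)
    return high, low


def filter_low(classification: GeneClassification) -> pd.DataFrame:
    """The low-expression (suppressed) half of :func:`filter_high_low`."""
    return filter_high_low(classification)[1]


def _pair_frame(
    a: TranscriptomeDataset,
    b: TranscriptomeDataset,
    min_fold: float,
    pseudo_count: float,
) -> pd.DataFrame:
    rows = []
    for gene in sorted(a.expression):
        va, vb = a.expression[gene], b.expression[gene]
        if va == 0 or vb == 0:
            ratio = (va + pseudo_count) / (vb + pseudo_count)
        else:
            ratio = va / vb
        if ratio > min_fold:
            direction = UP
        elif ratio < 1.0 / min_fold:
            direction = DOWN
        else:
            direction = UNCHANGED
        rows.append((gene, va, vb, ratio, direction))
    return pd.DataFrame(rows, columns=["gene", "value_A", "value_B", "ratio", "direction"])


def compare_expression(
    datasets: Sequence[TranscriptomeDataset],
    min_fold: float = 1.0,
    pseudo_count: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Up-/down-regulation of every gene, first dataset vs each of the others.

    Requires identical gene sets across datasets.  Ratio = value_A / value_B,
    with ``pseudo_count`` added to both sides whenever either value is zero;
    a gene is *up* when the ratio exceeds ``min_fold``, *down* when it falls
    below 1/``min_fold``, otherwise *unchanged*.
    """
    if len(datasets) < 2:
        raise ValidationError("compare_expression needs at least two datasets")
    if min_fold < 1.0:
        raise ValidationError(f"min_fold must be >= 1, got {min_fold}")
    reference = datasets[0]
    ref_genes = set(reference.expression)
    for other in datasets[1:]:
        mismatch = ref_genes ^ set(other.expression)
        if mismatch:
            raise ValidationError(
                f"gene sets differ between {reference.name} and {other.name}: "
                + ", ".join(sorted(mismatch)[:10])
            )
    return {
        f"{reference.name}_vs_{other.name}": _pair_frame(reference, other, min_fold, pseudo_count)
        for other in datasets[1:]
    }


def non_flux_reactions(context: ContextModel, fva: FvaResult) -> pd.DataFrame:
    """Reactions carrying no flux *because of* the transcriptome.

    A reaction is listed when its whole FVA range is zero (|flux| ≤ 1e-6) and
    its audit cause is expression-derived (an expression bound or a gene
    deletion); reactions that were already blocked in the source model do not
    appear.
    """
    expression_caused = context.expression_constrained_reactions()
    causes = {e.reaction: e.cause for e in context.audit}
    rows = []
    for rxn, (lo, hi) in fva.ranges.items():
        if max(abs(lo), abs(hi)) <= FLUX_EPS and rxn in expression_caused:
            rows.append((rxn, lo, hi, causes[rxn]))
    return pd.DataFrame(rows, columns=["reaction", "fva_min", "fva_max", "cause"])


def rate_limiting_reactions(context: ContextModel, fva: FvaResult) -> pd.DataFrame:
    """Reactions whose expression-derived cap equals their FVA extreme.

    These are the reactions where the transcriptome, not the network, limits
    the attainable rate: the applied upper bound matches the FVA maximum
    (symmetrically, the applied lower bound matches the FVA minimum for
    backward-irreversible flux) within 1e-6.
    """
    rows = []
    for rxn_id, entry in context.expression_bounds().items():
        if rxn_id not in fva.ranges:
            continue
        lo, hi = fva.ranges[rxn_id]
        rxn = context.model.reaction(rxn_id)
        binding = False
        if rxn.direction != "backward_irreversible" and entry.new_ub < entry.old_ub:
            binding |= abs(hi - entry.new_ub) <= FLUX_EPS
        if rxn.direction != "irreversible" and entry.new_lb > entry.old_lb:
            binding |= abs(lo - entry.new_lb) <= FLUX_EPS
        if binding:
            rows.append((rxn_id, entry.new_lb, entry.new_ub, lo, hi))
    return pd.DataFrame(
        rows, columns=["reaction", "applied_lb", "applied_ub", "fva_min", "fva_max"]
    )


def _shift_direction(value_a: float, value_b: float) -> tuple[float, str]:
    a_live, b_live = abs(value_a) > FLUX_EPS, abs(value_b) > FLUX_EPS
    if a_live and not b_live:
        return math.inf, NEW
    if b_live and not a_live:
        return 0.0, LOST
    if not a_live and not b_live:
        return 1.0, UNCHANGED
    ratio = value_a / value_b
    if ratio > 1.0 + RATIO_TOL:
        return ratio, UP
    if ratio < 1.0 - RATIO_TOL:
        return ratio, DOWN
    return ratio, UNCHANGED


def flux_shifts(fva_a: FvaResult, fva_b: FvaResult) -> pd.DataFrame:
    """FVA flux-range ratios between two phenotypes, per reaction.

    Both the min-flux and the max-flux ratios (A/B) are reported; the
    direction call comes from the max ratio.  A reaction fluxing in A but not
    in B (|flux| ≤ 1e-6) is *new* with an infinite sentinel ratio; the mirror
    case is *lost* with sentinel 0.
    """
    if set(fva_a.ranges) != set(fva_b.ranges):
        raise ValidationError("flux_shifts requires identical reaction sets")
    rows = []
    for rxn in fva_a.ranges:
        min_a, max_a = fva_a.ranges[rxn]
        min_b, max_b = fva_b.ranges[rxn]
        ratio_min, _ = _shift_direction(min_a, min_b)
        ratio_max, direction = _shift_direction(max_a, max_b)
        rows.append((rxn, min_a, max_a, min_b, max_b, ratio_min, ratio_max, direction))
    return pd.DataFrame(
        rows,
        columns=[
            "reaction", "min_A", "max_A", "min_B", "max_B",
            "ratio_min", "ratio_max", "direction",
        ],
    )
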