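"""Linear-programming services: FBA, FVA, gene-deletion growth ratios, and
per-reaction minimum-growth requirements.

The LP formulation is the standard constraint-based one — maximize (or
minimize) the objective flux subject to steady state ``S v = 0`` and the
bounds ``lb ≤ v ≤ ub`` — solved through cobrapy/optlang.  Only the objective
value of an FBA solution is unique; the flux vector is one optimum among
possibly many and is reported as-is.  FVA is the place where alternate optima
matter: it reports, per reaction, the attainable flux range subject to the
objective staying at a stated fraction of its optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from .errors import OptimizationError
from .gpr import boolean_evaluate, parse_gpr
from .model_io import MetabolicModel, to_cobra_model

__all__ = [
    "FluxSolution",
    "FvaResult",
    "fba",
    "fva",
    "apply_gene_knockout",
    "single_gene_deletion",
    "min_growth_requirements",
]

FLUX_EPS = 1e-6  # below this magnitude a flux is treated as zero


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: dict[str, float]
    status: Literal["optimal", "infeasible", "unbounded"]


@dataclass
class FvaResult:
    """Per-reaction (min flux, max flux) at a stated fraction of the optimum."""

    ranges: dict[str, tuple[float, float]]
    fraction_of_optimum: float

    def minimum(self, reaction_id: str) -> float:
        return self.ranges[reaction_id][0]

    def maximum(self, reaction_id: str) -> float:
        return self.ranges[reaction_id][1]

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.ranges)


def _unwrap(model) -> MetabolicModel:
    # accepts a MetabolicModel or anything carrying one under .model (ContextModel)
    return getattr(model, "model", model)


def fba(model, sense: Literal["maximize", "minimize"] = "maximize") -> FluxSolution:
    """Flux balance analysis; the status is reported faithfully, never a silent zero."""
    mm = _unwrap(model)
    if mm.objective_reaction is None:
        raise OptimizationError("model has no objective reaction")
    cm = to_cobra_model(mm)
    cm.objective_direction = "max" if sense == "maximize" else "min"
    solution = cm.optimize()
    status = solution.status
    if status == "optimal":
        return FluxSolution(
            objective_value=float(solution.objective_value),
            fluxes={r: float(v) for r, v in solution.fluxes.items()},
            status="optimal",
        )
    if status in ("infeasible", "unbounded"):
        return FluxSolution(objective_value=float("nan"), fluxes={}, status=status)
    raise OptimizationError(f"solver failure: status {status!r}")


def fva(
    model,
    fraction_of_optimum: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
) -> FvaResult:
    """Flux variability analysis: per-reaction min/max flux with the objective
    held at ``fraction_of_optimum`` × its FBA optimum."""
    from cobra.flux_analysis import flux_variability_analysis

    mm = _unwrap(model)
    if mm.objective_reaction is None:
        raise OptimizationError("model has no objective reaction")
    cm = to_cobra_model(mm)
    reaction_list = list(reactions) if reactions is not None else None
    try:
        frame = flux_variability_analysis(
            cm, reaction_list=reaction_list, fraction_of_optimum=fraction_of_optimum
        )
    except Exception as exc:
        raise OptimizationError(f"FVA failed at fraction {fraction_of_optimum}: {exc}") from exc
    ranges = {
        str(rid): (float(row["minimum"]), float(row["maximum"]))
        for rid, row in frame.iterrows()
    }
    return FvaResult(ranges=ranges, fraction_of_optimum=fraction_of_optimum)


def apply_gene_knockout(
    model: MetabolicModel, genes: set[str]
) -> tuple[MetabolicModel, list[str]]:
    """Boolean GPR knockout: zero the bounds of every reaction whose GPR can no
    longer be satisfied with ``genes`` absent.  Returns (copy, blocked ids)."""
    knocked = model.copy()
    blocked: list[str] = []
    for rxn in knocked.reactions:
        expr = parse_gpr(rxn.gpr)
        if expr is not None and not boolean_evaluate(expr, genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
            blocked.append(rxn.id)
    return knocked, blocked


def single_gene_deletion(model, gene: str) -> float:
    """grRatio of one gene: deletion-strain FBA growth / wild-type FBA growth.

    A deletion that leaves the model infeasible counts as zero growth.  The
    wild-type optimum must be positive for the ratio to be defined.
    """
    mm = _unwrap(model)
    wild_type = fba(mm)
    if wild_type.status != "optimal" or wild_type.objective_value <= FLUX_EPS:
        raise OptimizationError(
            "grRatio undefined: wild-type FBA optimum is zero or the model is infeasible"
        )
    knocked, blocked = apply_gene_knockout(mm, {gene})
    if not blocked:
        return 1.0
    deleted = fba(knocked)
    growth = deleted.objective_value if deleted.status == "optimal" else 0.0
    return float(growth / wild_type.objective_value)


def min_growth_requirements(aux_model) -> dict[str, float]:
    """Per-reaction minimum flux magnitude required to sustain optimal growth.

    Growth is fixed at the auxiliary model's FBA optimum and each reaction's
    requirement is the smallest |v| it can carry there (from FVA at fraction
    1.0): zero when the FVA range straddles zero, else the nearer range edge.
    """
    mm = _unwrap(aux_model)
    solution = fba(mm)
    if solution.status != "optimal":
        raise OptimizationError(
            f"auxiliary model has no optimum (status {solution.status}); "
            "cannot fix growth for minimum-requirement analysis"
        )
    result = fva(mm, fraction_of_optimum=1.0)
    requirements: dict[str, float] = {}
    for rxn, (lo, hi) in result.ranges.items():
        if lo <= FLUX_EPS and hi >= -FLUX_EPS:  # range straddles zero (within solver noise)
            requirements[rxn] = 0.0
        else:
            requirements[rxn] = min(abs(lo), abs(hi))
    return requirements
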