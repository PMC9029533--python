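"""Deterministic toy metabolic models and synthetic transcriptomes.

The toy model is a linear uptake→…→biomass chain with unit stoichiometry,
optionally widened with redundant parallel branches, an isozyme-gated step
(GPR ``gA or gB``) and an enzyme-complex-gated step (GPR ``gC and gD``).  Its
FBA optimum equals the uptake capacity, which makes hand-computed LP answers
available for every test.

Synthetic transcriptomes draw per-gene read counts from one of two log-normal
components (a low and a high expression mode, the standard shape for RNA-seq
counts); the planted high/low labels are returned so that threshold
classifiers can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .model_io import MetabolicModel, Reaction, TranscriptomeDataset

__all__ = ["ToySpec", "generate_toy_model", "generate_transcriptome"]


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the generated toy network.

    ``n_linear`` is the chain length in metabolites (≥2, giving ``n_linear-1``
    internal reactions); ``n_parallel`` ≥ 2 adds that many redundant branches
    (including the original) for the first chain step, each with capacity equal
    to the uptake bound.
    """

    n_linear: int = 3
    n_parallel: int = 0
    with_isozymes: bool = False
    with_complex: bool = False
    uptake: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_linear < 2:
            raise ValueError("n_linear must be >= 2")
        if self.n_parallel == 1:
            raise ValueError("n_parallel must be 0 or >= 2")


def generate_toy_model(spec: ToySpec = ToySpec()) -> MetabolicModel:
    """Build the toy chain model; deterministic for a given spec.

    Layout: ``EX_S`` imports M1 (bounds (−uptake, 0)), internal reactions
    ``R1..R{n-1}`` convert M_i → M_{i+1} (bounds (0, 1000)), and ``BIOMASS``
    drains the last metabolite (objective).  R1 carries the isozyme GPR when
    requested, R2 the complex GPR; every other internal reaction gets its own
    single gene ``g<i>``.
    """
    n_internal = spec.n_linear - 1
    metabolites = [f"M{i}" for i in range(1, spec.n_linear + 1)]
    reactions: list[Reaction] = []
    stoich: dict[tuple[str, str], float] = {}

    reactions.append(Reaction("EX_S", -spec.uptake, 0.0))
    stoich[("M1", "EX_S")] = -1.0

    for i in range(1, n_internal + 1):
        if i == 1 and spec.with_isozymes:
            gpr = "gA or gB"
        elif i == 2 and spec.with_complex:
            gpr = "gC and gD"
        else:
            gpr = f"g{i}"
        ub = spec.uptake if (i == 1 and spec.n_parallel >= 2) else 1000.0
        rxn = Reaction(f"R{i}", 0.0, ub, gpr)
        reactions.append(rxn)
        stoich[(f"M{i}", rxn.id)] = -1.0
        stoich[(f"M{i + 1}", rxn.id)] = 1.0

    # redundant branches parallel to R1 (same substrate/product, own genes)
    for j in range(2, spec.n_parallel + 1):
        rxn = Reaction(f"P{j}", 0.0, spec.uptake, f"gP{j}")
        reactions.append(rxn)
        stoich[("M1", rxn.id)] = -1.0
        stoich[("M2", rxn.id)] = 1.0

    reactions.append(Reaction("BIOMASS", 0.0, 1000.0))
    stoich[(metabolites[-1], "BIOMASS")] = -1.0

    genes = sorted({g for r in reactions for g in _gpr_gene_ids(r.gpr)})
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        stoichiometry=stoich,
        objective_reaction="BIOMASS",
    )


def _gpr_gene_ids(gpr: str) -> set[str]:
    from .gpr import parse_gpr

    expr = parse_gpr(gpr)
    return expr.genes() if expr is not None else set()


def generate_transcriptome(
    genes: Sequence[str],
    n_samples: int = 3,
    meanlog: tuple[float, float] = (3.0, 7.0),
    sdlog: tuple[float, float] = (0.5, 0.5),
    planted_labels: Optional[Mapping[str, str]] = None,
    phenotype: str = "SYN",
    seed: int = 0,
) -> tuple[list[TranscriptomeDataset], dict[str, str]]:
    """Draw synthetic per-gene expression from two log-normal modes.

    Each gene belongs to the ``"low"`` or ``"high"`` component (given via
    ``planted_labels`` or assigned deterministically: first half high, rest
    low) and keeps that label across samples.  ``meanlog``/``sdlog`` are the
    (low, high) log-scale parameters.  Returns the sample datasets and the
    planted labels; identical seeds give identical values.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    if planted_labels is None:
        half = len(genes) // 2
        planted_labels = {g: ("high" if i < half else "low") for i, g in enumerate(genes)}
    labels = dict(planted_labels)
    unknown = {lab for lab in labels.values()} - {"low", "high"}
    if unknown:
        raise ValueError(f"labels must be 'low'/'high', got {sorted(unknown)}")
    datasets = []
    for s in range(1, n_samples + 1):
        expression = {}
        for gene in genes:
            idx = 1 if labels[gene] == "high" else 0
            expression[gene] = float(rng.lognormal(mean=meanlog[idx], sigma=sdlog[idx]))
        datasets.append(
            TranscriptomeDataset(phenotype=phenotype, sample=f"S{s}", expression=expression)
        )
    return datasets, labels
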