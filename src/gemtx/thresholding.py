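"""Expressed/suppressed gene classification under global and local thresholds.

Three approaches are supported:

* **GT1** — one global threshold; a gene is expressed iff its value is
  strictly above it.
* **LT1** — one global threshold plus per-gene local thresholds computed
  across replicate samples of the same phenotype.  Values at or below the
  global cutoff are suppressed outright; values above it must additionally
  exceed the gene's local threshold (genes without a local threshold keep the
  global decision).
* **LT2** — lower and upper global thresholds.  Above the upper cutoff is
  expressed, below the lower cutoff suppressed, and the middle zone is decided
  per gene by its local threshold (no local threshold → suppressed).

Ties are resolved strictly: a value equal to a threshold is *not* above it.
Global thresholds may be exact values or percentiles of the pooled expression
values of every loaded sample (linear interpolation between closest ranks).
Local thresholds are the arithmetic mean of a gene's values over the samples
in which it was measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .model_io import TranscriptomeDataset

__all__ = [
    "ThresholdSpec",
    "ThresholdConfig",
    "GeneClassification",
    "resolve_threshold",
    "compute_local_thresholds",
    "classify",
]

EXPRESSED = "expressed"
SUPPRESSED = "suppressed"


@dataclass(frozen=True)
class ThresholdSpec:
    """A global threshold given either as an exact value or as a percentile."""

    mode: Literal["exact", "percentile"]
    value: float

    def __post_init__(self) -> None:
        if self.mode == "percentile" and not (0 <= self.value <= 100):
            raise ValidationError(f"percentile must lie in [0, 100], got {self.value}")

    @classmethod
    def parse(cls, text: str | float) -> "ThresholdSpec":
        """Parse ``130`` / ``"130"`` as exact or ``"p75"`` as the 75th percentile."""
        if isinstance(text, (int, float)):
            return cls("exact", float(text))
        text = text.strip()
        if text.lower().startswith("p"):
            return cls("percentile", float(text[1:]))
        return cls("exact", float(text))


@dataclass(frozen=True)
class ThresholdConfig:
    approach: Literal["GT1", "LT1", "LT2"]
    lower_global: ThresholdSpec
    upper_global: Optional[ThresholdSpec] = None

    def __post_init__(self) -> None:
        if self.approach == "LT2" and self.upper_global is None:
            raise ValidationError("LT2 requires both a lower and an upper global threshold")
        if self.approach != "LT2" and self.upper_global is not None:
            raise ValidationError(f"{self.approach} uses only lower_global")


@dataclass
class GeneClassification:
    """Per-gene expressed/suppressed status with the thresholds that decided it."""

    phenotype: str
    sample: str
    status: dict[str, str]
    applied: dict[str, float]
    resolved_globals: tuple[float, ...]
    values: dict[str, float] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.phenotype}_{self.sample}" if self.sample else self.phenotype

    def expressed_genes(self) -> list[str]:
        return [g for g, s in self.status.items() if s == EXPRESSED]

    def suppressed_genes(self) -> list[str]:
        return [g for g, s in self.status.items() if s == SUPPRESSED]


def resolve_threshold(spec: ThresholdSpec, values: Sequence[float] | None = None) -> float:
    """Turn a threshold spec into a number.

    Percentile mode takes the requested percentile of the pooled expression
    values (all samples of the run, zeros included) with linear interpolation;
    exact mode returns the value unchanged.
    """
    if spec.mode == "exact":
        return float(spec.value)
    if values is None or len(values) == 0:
        raise ValidationError("percentile threshold requires a non-empty expression pool")
    return float(np.percentile(np.asarray(values, dtype=float), spec.value))


def compute_local_thresholds(
    samples: Sequence[TranscriptomeDataset],
) -> dict[str, float]:
    """Per-gene local threshold: mean expression across same-phenotype samples.

    Requires at least two samples; a gene contributes only from samples where
    it was measured.
    """
    if len(samples) < 2:
        raise ValidationError(
            "local thresholds need at least two samples of the same condition; "
            "use the GT1 approach for a single sample"
        )
    phenotypes = {s.phenotype for s in samples}
    if len(phenotypes) != 1:
        raise ValidationError(f"samples span multiple phenotypes: {sorted(phenotypes)}")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for sample in samples:
        for gene, value in sample.expression.items():
            sums[gene] = sums.get(gene, 0.0) + value
            counts[gene] = counts.get(gene, 0) + 1
    return {gene: sums[gene] / counts[gene] for gene in sums}


def _pooled(datasets: Iterable[TranscriptomeDataset]) -> list[float]:
    pool: list[float] = []
    for ds in datasets:
        pool.extend(ds.expression.values())
    return pool


def resolve_config(
    config: ThresholdConfig, datasets: Sequence[TranscriptomeDataset]
) -> tuple[float, Optional[float]]:
    """Resolve the config's global specs against the pooled values of a run."""
    pool = _pooled(datasets)
    lower = resolve_threshold(config.lower_global, pool)
    upper = resolve_threshold(config.upper_global, pool) if config.upper_global else None
    if upper is not None and lower > upper:
        raise ValidationError(f"resolved lower threshold {lower} exceeds upper threshold {upper}")
    return lower, upper


def classify(
    dataset: TranscriptomeDataset,
    config: ThresholdConfig,
    locals: Optional[Mapping[str, float]] = None,
    resolved: Optional[tuple[float, Optional[float]]] = None,
) -> GeneClassification:
    """Classify every gene of one sample as expressed or suppressed.

    ``locals`` must be supplied for LT1/LT2 (see
    :func:`compute_local_thresholds`).  ``resolved`` can carry pre-resolved
    global thresholds (needed when percentile specs should be resolved against
    the whole run rather than this sample alone); by default the specs are
    resolved against this dataset's own values.
    """
    if config.approach in ("LT1", "LT2") and locals is None:
        raise ValidationError(f"{config.approach} requires local thresholds")
    if resolved is None:
        resolved = resolve_config(config, [dataset])
    lower, upper = resolved
    locals = locals or {}

    status: dict[str, str] = {}
    applied: dict[str, float] = {}
    for gene, value in dataset.expression.items():
        if config.approach == "GT1":
            status[gene] = EXPRESSED if value > lower else SUPPRESSED
            applied[gene] = lower
        elif config.approach == "LT1":
            if value <= lower:
                status[gene], applied[gene] = SUPPRESSED, lower
            elif gene in locals:
                status[gene] = EXPRESSED if value > locals[gene] else SUPPRESSED
                applied[gene] = locals[gene]
            else:  # no local threshold: the global decision stands
                status[gene], applied[gene] = EXPRESSED, lower
        else:  # LT2; boundaries fall into the locally decided middle zone
            assert upper is not None
            if value > upper:
                status[gene], applied[gene] = EXPRESSED, upper
            elif value < lower:
                status[gene], applied[gene] = SUPPRESSED, lower
            elif gene in locals:
                status[gene] = EXPRESSED if value > locals[gene] else SUPPRESSED
                applied[gene] = locals[gene]
            else:  # middle zone, no local evidence: conservative call
                status[gene], applied[gene] = SUPPRESSED, upper
    globals_out = (lower,) if upper is None else (lower, upper)
    return GeneClassification(
        phenotype=dataset.phenotype,
        sample=dataset.sample,
        status=status,
        applied=applied,
        resolved_globals=globals_out,
        values=dict(dataset.expression),
    )
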