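"""Readers and writers for metabolic models, transcriptomes, media and reports.

Models are accepted as SBML Level 3 (FBC), as a small JSON dialect, or as a
tabular dialect (``reactions.csv`` + ``stoich.csv``) convenient for tests and
toy fixtures.  Transcriptome tables are spreadsheets (one sheet per sample,
columns ``GeneId``/``Data``) or equivalent CSV files.  All analysis results go
back out as spreadsheets or CSV through :func:`write_report`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ModelFormatError, SchemaError, ValidationError

__all__ = [
    "Reaction",
    "MetabolicModel",
    "TranscriptomeDataset",
    "MediumComposition",
    "read_model",
    "write_model",
    "to_cobra_model",
    "from_cobra_model",
    "read_transcriptome",
    "read_medium",
    "write_report",
    "group_by_phenotype",
    "split_sheet_name",
]

GROWTH_RATE_KEY = "growth_rate"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    """A reaction with flux bounds (mmol·g⁻¹·h⁻¹) and a GPR rule string.

    ``direction`` is derived from the bounds: a reaction is *irreversible*
    when it can only run forward (lb ≥ 0), *backward irreversible* when it can
    only run backward (ub ≤ 0), and *reversible* otherwise.
    """

    id: str
    lower_bound: float
    upper_bound: float
    gpr: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def direction(self) -> str:
        if self.lower_bound >= 0:
            return "irreversible"
        if self.upper_bound <= 0:
            return "backward_irreversible"
        return "reversible"


@dataclass
class MetabolicModel:
    """A stoichiometric model: metabolites × reactions, genes, and an objective.

    ``stoichiometry`` maps ``(metabolite_id, reaction_id)`` to its coefficient;
    only nonzero entries are stored.
    """

    metabolites: list[str]
    reactions: list[Reaction]
    genes: list[str]
    stoichiometry: dict[tuple[str, str], float]
    objective_reaction: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rxn_ids = {r.id for r in self.reactions}
        if len(rxn_ids) != len(self.reactions):
            raise ValidationError("duplicate reaction ids in model")
        met_ids = set(self.metabolites)
        for (met, rxn), coef in self.stoichiometry.items():
            if coef == 0:
                continue
            if met not in met_ids:
                raise ValidationError(f"stoichiometry references undeclared metabolite {met!r}")
            if rxn not in rxn_ids:
                raise ValidationError(f"stoichiometry references undeclared reaction {rxn!r}")
        if self.objective_reaction is not None and self.objective_reaction not in rxn_ids:
            raise ValidationError(
                f"objective reaction {self.objective_reaction!r} is not a declared reaction"
            )
        declared = set(self.genes)
        missing = sorted(self.gpr_genes() - declared)
        if missing:
            raise ValidationError(
                "GPR rules reference genes not declared in the model: " + ", ".join(missing)
            )

    def gpr_genes(self) -> set[str]:
        from .gpr import parse_gpr  # deferred: gpr has no dependency on this module

        found: set[str] = set()
        for rxn in self.reactions:
            expr = parse_gpr(rxn.gpr)
            if expr is not None:
                found |= expr.genes()
        return found

    def reaction(self, reaction_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == reaction_id:
                return rxn
        raise KeyError(reaction_id)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def exchange_reactions(self) -> list[str]:
        """Boundary reactions: those touching exactly one metabolite."""
        counts: dict[str, int] = {r.id: 0 for r in self.reactions}
        for (_, rxn), coef in self.stoichiometry.items():
            if coef != 0:
                counts[rxn] += 1
        return [r.id for r in self.reactions if counts[r.id] == 1]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[replace(r) for r in self.reactions],
            genes=list(self.genes),
            stoichiometry=dict(self.stoichiometry),
            objective_reaction=self.objective_reaction,
        )


@dataclass
class TranscriptomeDataset:
    """One sample's gene-expression table (reads or normalized counts ≥ 0)."""

    phenotype: str
    sample: str
    expression: dict[str, float] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.phenotype}_{self.sample}" if self.sample else self.phenotype

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.expression.items() if v < 0 or not math.isfinite(v)}
        if bad:
            raise ValidationError(f"negative or non-finite expression values: {bad}")


@dataclass
class MediumComposition:
    """Exchange-reaction bounds of the growth medium, plus an optional growth rate (h⁻¹)."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    growth_rate: float | None = None

    def __post_init__(self) -> None:
        for rxn, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ValidationError(f"medium entry {rxn!r}: lower bound {lb} > upper bound {ub}")


# ---------------------------------------------------------------------------
# Model reading / writing
# ---------------------------------------------------------------------------

def _infer_model_format(path: Path) -> str:
    if path.is_dir() or path.name == "reactions.csv":
        return "tabular"
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ModelFormatError(f"cannot infer model format from {path}")


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from SBML, the JSON dialect, or the tabular dialect.

    GPR strings are preserved verbatim; reaction direction is classified from
    the bounds on access.
    """
    path = Path(path)
    fmt = format or _infer_model_format(path)
    if fmt == "sbml":
        import cobra.io

        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml errors are not a stable class
            raise ModelFormatError(f"cannot parse SBML file {path}: {exc}") from exc
        return from_cobra_model(cm)
    if fmt == "json":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"cannot parse JSON model {path}: {exc}") from exc
        return _model_from_payload(payload)
    if fmt == "tabular":
        return _read_tabular_model(path)
    raise ModelFormatError(f"unknown model format {fmt!r}")


def _model_from_payload(payload: Mapping) -> MetabolicModel:
    try:
        reactions = [
            Reaction(
                id=str(r["id"]),
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=str(r.get("gpr", "") or ""),
            )
            for r in payload["reactions"]
        ]
        stoich = {
            (str(m), str(r)): float(c) for m, r, c in payload["stoichiometry"]
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed model payload: {exc}") from exc
    metabolites = payload.get("metabolites") or sorted({m for (m, _) in stoich})
    objective = payload.get("objective_reaction")
    genes = payload.get("genes")
    if genes is None:
        # genes not declared: derive them from the GPR rules
        from .gpr import parse_gpr

        derived: set[str] = set()
        for r in reactions:
            expr = parse_gpr(r.gpr)
            if expr is not None:
                derived |= expr.genes()
        genes = sorted(derived)
    return MetabolicModel(
        metabolites=list(metabolites),
        reactions=reactions,
        genes=list(genes),
        stoichiometry=stoich,
        objective_reaction=objective,
    )


def _read_tabular_model(path: Path) -> MetabolicModel:
    """Tabular dialect: ``reactions.csv`` (id, lb, ub, gpr, objective) + ``stoich.csv``."""
    base = path if path.is_dir() else path.parent
    rxn_path = base / "reactions.csv"
    stoich_path = base / "stoich.csv"
    for p in (rxn_path, stoich_path):
        if not p.exists():
            raise ModelFormatError(f"tabular model file missing: {p}")
    rxn_df = pd.read_csv(rxn_path, dtype={"id": str, "gpr": str}, keep_default_na=False)
    required = {"id", "lower_bound", "upper_bound", "gpr", "objective"}
    if not required.issubset(rxn_df.columns):
        raise ModelFormatError(
            f"reactions.csv missing columns: {sorted(required - set(rxn_df.columns))}"
        )
    stoich_df = pd.read_csv(stoich_path, dtype={"metabolite": str, "reaction": str})
    if not {"metabolite", "reaction", "coefficient"}.issubset(stoich_df.columns):
        raise ModelFormatError("stoich.csv must have columns metabolite, reaction, coefficient")
    reactions = [
        Reaction(row.id, float(row.lower_bound), float(row.upper_bound), row.gpr or "")
        for row in rxn_df.itertuples()
    ]
    objective_rows = rxn_df[rxn_df["objective"].astype(int) != 0]
    objective = str(objective_rows.iloc[0]["id"]) if len(objective_rows) else None
    stoich = {
        (row.metabolite, row.reaction): float(row.coefficient)
        for row in stoich_df.itertuples()
        if row.coefficient != 0
    }
    return _model_from_payload(
        {
            "metabolites": sorted({m for (m, _) in stoich}),
            "reactions": [
                {"id": r.id, "lower_bound": r.lower_bound, "upper_bound": r.upper_bound, "gpr": r.gpr}
                for r in reactions
            ],
            "stoichiometry": [[m, r, c] for (m, r), c in stoich.items()],
            "objective_reaction": objective,
        }
    )


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as SBML, JSON dialect, or the tabular dialect (a directory)."""
    path = Path(path)
    fmt = format or _infer_model_format(path)
    if fmt == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra_model(model), str(path))
        return
    if fmt == "json":
        payload = {
            "metabolites": model.metabolites,
            "genes": model.genes,
            "objective_reaction": model.objective_reaction,
            "reactions": [
                {"id": r.id, "lower_bound": r.lower_bound, "upper_bound": r.upper_bound, "gpr": r.gpr}
                for r in model.reactions
            ],
            "stoichiometry": [[m, r, c] for (m, r), c in sorted(model.stoichiometry.items())],
        }
        Path(path).write_text(json.dumps(payload, indent=1))
        return
    if fmt == "tabular":
        base = path
        base.mkdir(parents=True, exist_ok=True)
        rxn_df = pd.DataFrame(
            {
                "id": [r.id for r in model.reactions],
                "lower_bound": [r.lower_bound for r in model.reactions],
                "upper_bound": [r.upper_bound for r in model.reactions],
                "gpr": [r.gpr for r in model.reactions],
                "objective": [int(r.id == model.objective_reaction) for r in model.reactions],
            }
        )
        rxn_df.to_csv(base / "reactions.csv", index=False)
        rows = sorted(model.stoichiometry.items())
        stoich_df = pd.DataFrame(
            {
                "metabolite": [m for (m, _), _ in rows],
                "reaction": [r for (_, r), _ in rows],
                "coefficient": [c for _, c in rows],
            }
        )
        stoich_df.to_csv(base / "stoich.csv", index=False)
        return
    raise ModelFormatError(f"unknown model format {fmt!r}")


def to_cobra_model(model: MetabolicModel):
    """Convert to a :class:`cobra.Model` (used for SBML output and the LP layer)."""
    import cobra

    cm = cobra.Model("gemtx")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for cr, r in zip(rxns, model.reactions):
        coefs = {
            mets[m]: c for (m, rid), c in model.stoichiometry.items() if rid == r.id and c != 0
        }
        cr.add_metabolites(coefs)
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    if model.objective_reaction is not None:
        cm.objective = model.objective_reaction
    return cm


def from_cobra_model(cm) -> MetabolicModel:
    """Convert a :class:`cobra.Model` to the package's in-memory model."""
    from cobra.util.solver import linear_reaction_coefficients

    stoich: dict[tuple[str, str], float] = {}
    reactions = []
    for r in cm.reactions:
        reactions.append(
            Reaction(r.id, float(r.lower_bound), float(r.upper_bound), r.gene_reaction_rule or "")
        )
        for met, coef in r.metabolites.items():
            if coef != 0:
                stoich[(met.id, r.id)] = float(coef)
    objective = None
    coeffs = linear_reaction_coefficients(cm)
    if coeffs:
        objective = max(coeffs, key=lambda rx: abs(coeffs[rx])).id
    return MetabolicModel(
        metabolites=[m.id for m in cm.metabolites],
        reactions=reactions,
        genes=[g.id for g in cm.genes],
        stoichiometry=stoich,
        objective_reaction=objective,
    )


# ---------------------------------------------------------------------------
# Transcriptome reading
# ---------------------------------------------------------------------------

def split_sheet_name(name: str) -> tuple[str, str]:
    """Split ``<phenotype>_<sample>`` on the last underscore.

    A name without an underscore is a phenotype with a single anonymous sample.
    """
    name = name.strip()
    if "_" in name:
        phenotype, _, sample = name.rpartition("_")
        return phenotype, sample
    return name, ""


def _dataset_from_frame(df: pd.DataFrame, sheet: str) -> TranscriptomeDataset:
    if df.empty and df.columns.size == 0:
        raise SchemaError(f"sheet {sheet!r} is empty")
    missing = {"GeneId", "Data"} - set(df.columns)
    if missing:
        raise SchemaError(f"sheet {sheet!r} missing required columns: {sorted(missing)}")
    df = df[["GeneId", "Data"]].dropna(how="all")
    if df.empty:
        raise SchemaError(f"sheet {sheet!r} has no data rows")
    expression: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        gene = str(row.GeneId)
        try:
            value = float(row.Data)
        except (TypeError, ValueError):
            raise ValidationError(f"sheet {sheet!r} row {i}: non-numeric Data {row.Data!r}")
        if not math.isfinite(value) or value < 0:
            raise ValidationError(f"sheet {sheet!r} row {i}: negative or non-finite Data {value}")
        if gene in expression:
            raise ValidationError(f"sheet {sheet!r}: duplicate GeneId {gene!r}")
        expression[gene] = value
    phenotype, sample = split_sheet_name(sheet)
    return TranscriptomeDataset(phenotype=phenotype, sample=sample, expression=expression)


def read_transcriptome(path: str | Path) -> list[TranscriptomeDataset]:
    """Read transcriptome samples from an xlsx workbook (one sheet per sample)
    or a CSV file (sample name taken from the file stem).

    Each sheet must carry ``GeneId`` and ``Data`` columns; the sheet name
    encodes ``<phenotype>_<sample>``.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        datasets = [_dataset_from_frame(df, sheet) for sheet, df in sheets.items()]
    elif path.suffix.lower() in (".csv", ".tsv"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        datasets = [_dataset_from_frame(pd.read_csv(path, sep=sep), path.stem)]
    else:
        raise SchemaError(f"unsupported transcriptome file type: {path.suffix}")
    seen: set[tuple[str, str]] = set()
    for ds in datasets:
        key = (ds.phenotype, ds.sample)
        if key in seen:
            raise ValidationError(f"duplicate phenotype/sample pair {key}")
        seen.add(key)
    return datasets


def group_by_phenotype(
    datasets: Iterable[TranscriptomeDataset],
) -> dict[str, list[TranscriptomeDataset]]:
    """Partition samples by phenotype, preserving input order."""
    groups: dict[str, list[TranscriptomeDataset]] = {}
    for ds in datasets:
        groups.setdefault(ds.phenotype, []).append(ds)
    return groups


# ---------------------------------------------------------------------------
# Medium reading
# ---------------------------------------------------------------------------

def read_medium(path: str | Path) -> MediumComposition:
    """Read a medium-composition table: reaction id, lower bound, upper bound.

    A row whose reaction id is ``growth_rate`` (case-insensitive) carries the
    specific growth rate (h⁻¹) in the lower-bound column.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    elif path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
    else:
        raise SchemaError(f"unsupported medium file type: {path.suffix}")
    if df.shape[1] < 3:
        raise SchemaError("medium file needs at least 3 columns: reaction, lower, upper")
    bounds: dict[str, tuple[float, float]] = {}
    growth_rate = None
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rxn = str(row[0]).strip()
        if not rxn or rxn.lower() == "nan":
            continue
        if rxn.lower() == GROWTH_RATE_KEY:
            growth_rate = float(row[1])
            continue
        try:
            lb, ub = float(row[1]), float(row[2])
        except (TypeError, ValueError):
            raise ValidationError(f"medium row {i}: non-numeric bounds {row[1]!r}, {row[2]!r}")
        if lb > ub:
            raise ValidationError(f"medium row {i} ({rxn}): lower bound {lb} > upper bound {ub}")
        bounds[rxn] = (lb, ub)
    return MediumComposition(bounds=bounds, growth_rate=growth_rate)


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

_EXCEL_BAD = set('[]:*?/\\')


def _sheet_title(name: str) -> str:
    cleaned = "".join("_" if ch in _EXCEL_BAD else ch for ch in name)
    return cleaned[:31] or "sheet"


def write_report(
    results: Mapping[str, pd.DataFrame], path: str | Path, format: str = "xlsx"
) -> None:
    """Write task results, one sheet (xlsx) or one file (csv) per sheet name.

    Column order is taken from each DataFrame as given; an empty frame yields
    a header-only sheet.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            if not results:
                pd.DataFrame().to_excel(writer, sheet_name="empty", index=False)
            for sheet, df in results.items():
                df.to_excel(writer, sheet_name=_sheet_title(sheet), index=False)
    elif format == "csv":
        if len(results) == 1 and path.suffix.lower() == ".csv":
            next(iter(results.values())).to_csv(path, index=False)
        else:
            base = path if path.suffix == "" else path.with_suffix("")
            base.mkdir(parents=True, exist_ok=True)
            for sheet, df in results.items():
                df.to_csv(base / f"{sheet}.csv", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
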