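"""Readers and writers for the pipeline's tabular inputs.

Formats
-------
expression matrix
    Tab-delimited; first column probe-set ids, header row of sample ids,
    log2 intensities in the body.  No missing values.
sample sheet
    CSV with columns ``sample_id``, ``class_label``, ``timepoint``
    (timepoint empty for controls).  Free-text class labels are mapped to
    the three roles {control, modelA, modelB} via a configurable mapping,
    so sheets labelled e.g. "CLP"/"CS"/"control" load unchanged.
probe annotation
    Tab-delimited with columns ``probe_id``, ``gene_symbol``; several
    probes may share a gene symbol.  An empty gene symbol marks an
    unannotated probe (kept for probe-level statistics, excluded from
    gene-level collapsing).
gene sets
    GMT: one set per line, ``name<TAB>description<TAB>member...``.
    A member may carry a direction suffix ``SYMBOL|+1`` or ``SYMBOL|-1``
    giving the expected regulation sign; within a set, either every
    member has a direction or none does.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import CONTROL, MODEL_A, MODEL_B

ROLES = (CONTROL, MODEL_A, MODEL_B)

#: Accepts both the generator's role labels and the conventional murine
#: sepsis model names (CLP = cecal ligation and puncture -> modelA,
#: CS = cecal slurry -> modelB).
DEFAULT_CLASS_MAP = {
    "control": CONTROL,
    "healthy": CONTROL,
    "naive": CONTROL,
    "CLP": MODEL_A,
    "modelA": MODEL_A,
    "CS": MODEL_B,
    "modelB": MODEL_B,
}


@dataclass
class GeneSet:
    """A named gene list, optionally with expected regulation directions."""

    name: str
    genes: list[str]
    directions: dict[str, int] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        seen = set()
        for g in self.genes:
            if g in seen:
                raise ValidationError(
                    f"gene set {self.name!r} lists gene {g!r} more than once"
                )
            seen.add(g)
        if self.directions is not None:
            missing = [g for g in self.genes if g not in self.directions]
            if missing:
                raise ValidationError(
                    f"gene set {self.name!r}: directions missing for {missing}"
                )
            bad = {g: d for g, d in self.directions.items() if d not in (-1, 1)}
            if bad:
                raise ValidationError(
                    f"gene set {self.name!r}: directions must be +1/-1, got {bad}"
                )


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of an in-memory expression matrix."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids: {dups[:10]}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:10]}")
    try:
        values = matrix.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric expression value: {exc}") from exc
    if not np.isfinite(values).all():
        rows = matrix.index[~np.isfinite(values).all(axis=1)].tolist()
        raise ValidationError(
            f"missing or non-finite values in probes: {rows[:10]}"
        )
    return matrix.astype(float)


def read_expression(path) -> pd.DataFrame:
    """Read and validate a tab-delimited log2 expression matrix."""
    path = Path(path)
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    matrix.index.name = "probe_id"
    matrix.columns.name = "sample_id"
    for col in matrix.columns:
        if not pd.api.types.is_numeric_dtype(matrix[col]):
            bad = matrix[col][pd.to_numeric(matrix[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path}: non-numeric value(s) in sample {col!r} "
                f"at probes {bad.index.tolist()[:5]}"
            )
    return validate_expression(matrix)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_sample_annotation(
    path,
    class_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a sample sheet and map free-text class labels onto the three roles."""
    class_map = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "class_label"}
    if not required.issubset(table.columns):
        raise ValidationError(
            f"{path}: sample sheet needs columns {sorted(required)}, "
            f"found {list(table.columns)}"
        )
    if "timepoint" not in table.columns:
        table["timepoint"] = None
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    unknown = sorted(set(table["class_label"]) - set(class_map))
    if unknown:
        raise ValidationError(
            f"{path}: unknown class label(s) {unknown}; extend the class map"
        )
    table["class_label"] = table["class_label"].map(class_map)
    table["timepoint"] = table["timepoint"].where(table["timepoint"].notna(), None)
    annot = table.set_index("sample_id")[["class_label", "timepoint"]]
    bad = annot.index[(annot["class_label"] == CONTROL)
                      & annot["timepoint"].notna()].tolist()
    if bad:
        raise ValidationError(f"control samples carry a timepoint: {bad}")
    bad = annot.index[(annot["class_label"] != CONTROL)
                      & annot["timepoint"].isna()].tolist()
    if bad:
        raise ValidationError(f"septic samples missing a timepoint: {bad}")
    return annot


def read_probe_annotation(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_symbol"}
    if not required.issubset(table.columns):
        raise ValidationError(
            f"{path}: probe annotation needs columns {sorted(required)}"
        )
    if table["probe_id"].duplicated().any():
        dups = table.loc[table["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"{path}: duplicate probe ids {dups[:10]}")
    return table.set_index("probe_id")[["gene_symbol"]]


def align_annotations(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    probes: pd.DataFrame | None = None,
) -> None:
    """Verify annotations cover the matrix; raise listing what is missing."""
    missing = [s for s in matrix.columns if s not in samples.index]
    if missing:
        raise ValidationError(
            f"samples in matrix but not in annotation: {missing[:10]}"
        )
    if probes is not None:
        missing_p = matrix.index.difference(probes.index).tolist()
        if missing_p:
            raise ValidationError(
                f"probes in matrix but not in annotation: {missing_p[:10]}"
            )


def read_gene_sets(path) -> list[GeneSet]:
    """Parse a GMT file, honouring the optional ``|+1``/``|-1`` direction
    suffix dialect."""
    sets: list[GeneSet] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member"
                )
            name, description, *members = fields
            genes: list[str] = []
            directions: dict[str, int] = {}
            any_directed = False
            for member in members:
                if not member:
                    continue
                if "|" in member:
                    symbol, _, suffix = member.partition("|")
                    if suffix not in ("+1", "-1") or not symbol:
                        raise ValidationError(
                            f"{path}:{lineno}: malformed direction suffix "
                            f"{member!r} in set {name!r}"
                        )
                    genes.append(symbol)
                    directions[symbol] = int(suffix)
                    any_directed = True
                else:
                    genes.append(member)
            if any_directed and len(directions) != len(genes):
                undirected = [g for g in genes if g not in directions]
                raise ValidationError(
                    f"{path}:{lineno}: set {name!r} mixes directed and "
                    f"undirected members ({undirected})"
                )
            sets.append(GeneSet(name=name, genes=genes,
                                directions=directions if any_directed else None,
                                description=description))
    if not sets:
        raise ValidationError(f"{path}: no gene sets found")
    return sets


def write_gene_sets(sets: list[GeneSet], path) -> None:
    with open(path, "w") as handle:
        for gs in sets:
            if gs.directions is None:
                members = gs.genes
            else:
                members = [f"{g}|{gs.directions[g]:+d}" for g in gs.genes]
            handle.write("\t".join([gs.name, gs.description, *members]) + "\n")
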