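"""Parsing, filtering and assembly of chemical-protein association data.

Association tables are TSV files whose relevant columns are declared through a
:class:`ColumnMap`, so the same reader handles exports with arbitrary column
names and activity units.  Surviving records are collapsed into a binary
one-class interaction matrix ``R`` (chemicals x proteins) with identifier
registries in first-appearance order.  Matrices are interchanged in Matrix
Market coordinate format (``pattern`` field for binary matrices) with the
registries serialized alongside as plain-text line lists.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ParseError, ValidationError

#: Recognized provenance tags for an association record.  The four
#: ``drug_*`` tags mark curated database links that carry no assay value;
#: ``inhibition_assay`` marks records with a measured potency.
SOURCES = frozenset(
    {
        "inhibition_assay",
        "drug_target",
        "drug_enzyme",
        "drug_carrier",
        "drug_transporter",
        "other",
    }
)

#: Curated-link sources kept unconditionally by the activity filter.
CURATED_SOURCES = frozenset(
    {"drug_target", "drug_enzyme", "drug_carrier", "drug_transporter"}
)

#: Multipliers converting a declared concentration unit to molar.
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class ActivityRecord:
    """One chemical-protein association.

    ``activity_value`` is a molar concentration (e.g. an IC50) and is absent
    for curated links and for rows whose activity field did not parse.
    """

    chemical_id: str
    protein_id: str
    activity_value: float | None = None
    confidence: int | None = None
    source: str = "other"

    def __post_init__(self) -> None:
        if not self.chemical_id or not self.protein_id:
            raise ValidationError("chemical_id and protein_id must be non-empty")
        if self.activity_value is not None and not self.activity_value > 0:
            raise ValidationError(
                f"activity_value must be strictly positive, got {self.activity_value!r}"
            )
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source tag {self.source!r}")


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from the semantic fields to the columns of an association TSV.

    ``activity_unit`` declares the unit of the activity column; values are
    normalized to molar on parse.  Rows without a mapped source column are
    tagged ``default_source``.
    """

    chemical_id: str
    protein_id: str
    activity: str | None = None
    confidence: str | None = None
    source: str | None = None
    activity_unit: str = "M"
    default_source: str = "other"

    def __post_init__(self) -> None:
        if self.activity_unit not in _UNIT_TO_MOLAR:
            raise ValidationError(
                f"unknown activity unit {self.activity_unit!r}; "
                f"expected one of {sorted(_UNIT_TO_MOLAR)}"
            )
        if self.default_source not in SOURCES:
            raise ValidationError(f"unknown default source {self.default_source!r}")


def parse_association_table(path: str | os.PathLike, colmap: ColumnMap) -> list[ActivityRecord]:
    """Read a TSV association table into a list of :class:`ActivityRecord`.

    One record per data row, in file order.  Activity values that fail to
    parse as a positive number (``NA``, blanks, negatives) yield a record with
    ``activity_value`` absent rather than dropping the row.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"association table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = [colmap.chemical_id, colmap.protein_id]
    for optional in (colmap.activity, colmap.confidence, colmap.source):
        if optional is not None:
            needed.append(optional)
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"mapped column {col!r} missing from header {list(df.columns)}")

    factor = _UNIT_TO_MOLAR[colmap.activity_unit]
    records: list[ActivityRecord] = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        activity = None
        if colmap.activity is not None:
            try:
                value = float(row[colmap.activity])
            except (TypeError, ValueError):
                value = float("nan")
            if np.isfinite(value) and value > 0:
                activity = value * factor
        confidence = None
        if colmap.confidence is not None:
            try:
                confidence = int(float(row[colmap.confidence]))
            except (TypeError, ValueError):
                confidence = None
        source = colmap.default_source
        if colmap.source is not None:
            raw = str(row[colmap.source]).strip()
            source = raw if raw in SOURCES else "other"
        records.append(
            ActivityRecord(
                chemical_id=str(row[colmap.chemical_id]),
                protein_id=str(row[colmap.protein_id]),
                activity_value=activity,
                confidence=confidence,
                source=source,
            )
        )
    return records


def filter_activity_records(
    records: Iterable[ActivityRecord],
    ic50_max: float = 10e-6,
    min_confidence: int = 9,
) -> list[ActivityRecord]:
    """Keep high-confidence active associations.

    Curated database links (drug-target, drug-enzyme, drug-carrier,
    drug-transporter) are kept unconditionally: they carry no assay value.
    Inhibition-assay records survive iff their activity is at most ``ic50_max``
    (molar; default 10 uM) and their confidence is at least ``min_confidence``
    (default 9).  A missing activity or confidence on an assay record fails
    the filter.  Records with source ``other`` are dropped.  Order preserved;
    the operation is idempotent.
    """
    if not ic50_max > 0:
        raise ValidationError(f"ic50_max must be positive, got {ic50_max}")
    kept = []
    for rec in records:
        if rec.source in CURATED_SOURCES:
            kept.append(rec)
        elif rec.source == "inhibition_assay":
            if (
                rec.activity_value is not None
                and rec.activity_value <= ic50_max
                and rec.confidence is not None
                and rec.confidence >= min_confidence
            ):
                kept.append(rec)
    return kept


@dataclass
class InteractionMatrix:
    """Sparse binary chemical x protein interaction matrix with registries."""

    values: sp.csr_matrix
    chemical_ids: list[str]
    protein_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.values.eliminate_zeros()
        if self.values.shape != (len(self.chemical_ids), len(self.protein_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match registries "
                f"({len(self.chemical_ids)} chemicals, {len(self.protein_ids)} proteins)"
            )
        if len(set(self.chemical_ids)) != len(self.chemical_ids):
            raise ValidationError("duplicate chemical identifiers")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValidationError("duplicate protein identifiers")
        if self.values.nnz and not np.all(self.values.data == 1.0):
            raise ValidationError("interaction matrix entries must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.chemical_ids)

    @property
    def m(self) -> int:
        return len(self.protein_ids)

    @property
    def nnz(self) -> int:
        return int(self.values.nnz)


def build_interaction_matrix(
    records: Iterable[ActivityRecord],
    chemical_ids: Sequence[str] | None = None,
    protein_ids: Sequence[str] | None = None,
) -> InteractionMatrix:
    """Collapse records into a binary matrix; duplicates count once.

    When registries are omitted they are built from record identifiers in
    first-appearance order.  A record identifier absent from a supplied
    registry raises :class:`ValidationError` naming the id.
    """
    records = list(records)
    if chemical_ids is None:
        chemical_ids = list(dict.fromkeys(r.chemical_id for r in records))
    else:
        chemical_ids = list(chemical_ids)
    if protein_ids is None:
        protein_ids = list(dict.fromkeys(r.protein_id for r in records))
    else:
        protein_ids = list(protein_ids)
    chem_index = {c: i for i, c in enumerate(chemical_ids)}
    prot_index = {p: j for j, p in enumerate(protein_ids)}

    pairs = set()
    for rec in records:
        if rec.chemical_id not in chem_index:
            raise ValidationError(f"chemical id {rec.chemical_id!r} absent from registry")
        if rec.protein_id not in prot_index:
            raise ValidationError(f"protein id {rec.protein_id!r} absent from registry")
        pairs.add((chem_index[rec.chemical_id], prot_index[rec.protein_id]))

    shape = (len(chemical_ids), len(protein_ids))
    if pairs:
        rows, cols = zip(*sorted(pairs))
        values = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=shape, dtype=np.float64
        )
    else:
        values = sp.csr_matrix(shape, dtype=np.float64)
    return InteractionMatrix(values, chemical_ids, protein_ids)


def write_matrix(M: sp.spmatrix | np.ndarray, path: str | os.PathLike) -> None:
    """Write a matrix in Matrix Market format.

    Sparse binary matrices are written with the ``pattern`` field; everything
    else as ``real``.  1-based coordinate indices per the format standard.
    """
    if sp.issparse(M):
        M = M.tocoo()
        field = "pattern" if (M.nnz == 0 or np.all(M.data == 1.0)) else "real"
        scipy.io.mmwrite(os.fspath(path), M, field=field)
    else:
        scipy.io.mmwrite(os.fspath(path), np.asarray(M))


def read_matrix(path: str | os.PathLike) -> sp.coo_matrix | np.ndarray:
    """Read a Matrix Market file; malformed content raises :class:`ParseError`."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"matrix file not found: {path}")
    try:
        return scipy.io.mmread(os.fspath(path))
    except Exception as exc:  # scipy raises bare ValueError on truncation
        raise ParseError(f"malformed Matrix Market file {path}: {exc}") from exc


def write_id_list(ids: Sequence[str], path: str | os.PathLike) -> None:
    with io.open(path, "w", encoding="utf-8") as fh:
        for entry in ids:
            fh.write(f"{entry}\n")


def read_id_list(path: str | os.PathLike) -> list[str]:
    with io.open(path, "r", encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n")]


def save_interaction_matrix(im: InteractionMatrix, prefix: str | os.PathLike) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.chemicals.txt`` / ``.proteins.txt``."""
    prefix = os.fspath(prefix)
    write_matrix(im.values, prefix + ".mtx")
    write_id_list(im.chemical_ids, prefix + ".chemicals.txt")
    write_id_list(im.protein_ids, prefix + ".proteins.txt")


def load_interaction_matrix(prefix: str | os.PathLike) -> InteractionMatrix:
    prefix = os.fspath(prefix)
    values = sp.csr_matrix(read_matrix(prefix + ".mtx"))
    values.data[:] = 1.0
    return InteractionMatrix(
        values,
        read_id_list(prefix + ".chemicals.txt"),
        read_id_list(prefix + ".proteins.txt"),
    )
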