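"""Reading, validating, canonicalizing and filtering molecular toxicity records.

A :class:`ToxRecord` is one molecule–endpoint–value observation from one
source, before any curation.  Records are exchanged as plain CSV with the
header ``smiles,endpoint_id,value,units,source_id``.

Structure handling is delegated to RDKit: two SMILES strings denote the same
molecule exactly when their RDKit canonical forms are equal.  Element
filtering implements the curation rule used for the aggregated hackathon
datasets: a molecule is discarded if it contains no carbon atom, or any
element outside a fixed 13-element whitelist (hydrogen is always permitted —
the whitelist describes heavy-atom composition of organic toxicants, and a
literal reading would discard every molecule).

Salts and multi-fragment SMILES are kept as-is; no desalting or charge/
tautomer standardization is attempted.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

# RDKit logs every parse failure to stderr; errors are reported structurally.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Units",
    "Task",
    "ToxRecord",
    "EndpointSpec",
    "ElementWhitelist",
    "DEFAULT_WHITELIST",
    "InvalidRecordError",
    "RecordTableError",
    "canonicalize",
    "element_filter",
    "read_records",
    "write_records",
]


class Units(str, Enum):
    """Units a toxicity value may be expressed in."""

    MG_PER_KG = "mg_per_kg"
    MMOL_PER_KG = "mmol_per_kg"
    LOG10_MMOL_PER_KG = "log10_mmol_per_kg"
    BINARY = "binary"


class Task(str, Enum):
    REGRESSION = "regression"
    CLASSIFICATION = "classification"


class InvalidRecordError(ValueError):
    """A single record failed validation; carries the offending text."""

    def __init__(self, message: str, offending: str = "", row: int | None = None):
        self.offending = offending
        self.row = row
        super().__init__(message)


class RecordTableError(ValueError):
    """A CSV record table failed validation; lists offending row numbers."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        self.rows = list(rows)
        super().__init__(message)


@dataclass(frozen=True)
class ToxRecord:
    """One molecule–endpoint–value observation from one source.

    ``value`` is a dose on the scale given by ``units``, or a 0/1 label when
    ``units`` is binary.
    """

    smiles: str
    endpoint_id: str
    value: float
    units: Units
    source_id: str

    def __post_init__(self) -> None:
        if not self.smiles:
            raise InvalidRecordError("smiles must be non-empty", self.smiles)
        if not math.isfinite(self.value):
            raise InvalidRecordError(
                f"value must be finite, got {self.value!r}", self.smiles
            )
        if self.units == Units.BINARY and self.value not in (0.0, 1.0):
            raise InvalidRecordError(
                f"binary value must be 0 or 1, got {self.value!r}", self.smiles
            )


@dataclass(frozen=True)
class EndpointSpec:
    """A toxicity endpoint: its task type and canonical value scale."""

    endpoint_id: str
    task: Task
    canonical_units: Units

    def __post_init__(self) -> None:
        if self.task == Task.CLASSIFICATION and self.canonical_units != Units.BINARY:
            raise ValueError("classification endpoints must use binary units")


#: Heavy-atom elements admitted by the curation filter.
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"N", "I", "As", "O", "B", "Br", "F", "P", "Se", "S", "C", "Cl", "Si"}
)


@dataclass(frozen=True)
class ElementWhitelist:
    allowed: frozenset[str] = DEFAULT_ALLOWED_ELEMENTS

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.allowed


DEFAULT_WHITELIST = ElementWhitelist()


def canonicalize(smiles: str) -> str:
    """Return the RDKit canonical SMILES for ``smiles``.

    Two inputs denoting the same molecule map to the same output, and the
    function is idempotent.  Unparseable input raises
    :class:`InvalidRecordError` carrying the offending text; the caller
    decides whether to drop the record or abort.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidRecordError(f"unparseable SMILES: {smiles!r}", smiles)
    return Chem.MolToSmiles(mol)


def canonicalize_records(
    records: Iterable[ToxRecord], strict: bool = False
) -> tuple[list[ToxRecord], list[tuple[ToxRecord, str]]]:
    """Canonicalize the SMILES of every record.

    Returns ``(canonicalized, failed)`` where ``failed`` pairs each
    unparseable record with its error message.  With ``strict=True`` the
    first failure aborts instead.
    """
    out: list[ToxRecord] = []
    failed: list[tuple[ToxRecord, str]] = []
    for rec in records:
        try:
            smi = canonicalize(rec.smiles)
        except InvalidRecordError as err:
            if strict:
                raise
            failed.append((rec, str(err)))
            continue
        out.append(
            ToxRecord(smi, rec.endpoint_id, rec.value, rec.units, rec.source_id)
        )
    return out, failed


@dataclass
class RemovedRecord:
    record: ToxRecord
    reason: str


def element_filter(
    records: Sequence[ToxRecord],
    whitelist: ElementWhitelist = DEFAULT_WHITELIST,
) -> tuple[list[ToxRecord], list[RemovedRecord]]:
    """Partition ``records`` into kept and removed by elemental composition.

    A record is removed iff its molecule has no carbon atom, or contains any
    heavy element outside the whitelist.  Hydrogen (implicit or explicit) is
    always permitted.  Reasons are ``no_carbon`` or
    ``disallowed_element:<symbol>`` (first offending symbol in atom order).
    ``kept + removed`` is exactly the input, in order.
    """
    kept: list[ToxRecord] = []
    removed: list[RemovedRecord] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise InvalidRecordError(
                f"unparseable SMILES (canonicalize first): {rec.smiles!r}",
                rec.smiles,
            )
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        if "C" not in symbols:
            removed.append(RemovedRecord(rec, "no_carbon"))
            continue
        bad = next((s for s in symbols if s != "H" and s not in whitelist), None)
        if bad is not None:
            removed.append(RemovedRecord(rec, f"disallowed_element:{bad}"))
        else:
            kept.append(rec)
    return kept, removed


CSV_HEADER = ["smiles", "endpoint_id", "value", "units", "source_id"]


def read_records(path: str | Path) -> list[ToxRecord]:
    """Read a record table from CSV.

    The file must carry the header ``smiles,endpoint_id,value,units,source_id``.
    Malformed rows raise :class:`RecordTableError` naming the file line
    numbers (the header is line 1).
    """
    path = Path(path)
    records: list[ToxRecord] = []
    bad_rows: list[int] = []
    messages: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            f.strip() for f in reader.fieldnames
        ] != CSV_HEADER:
            raise RecordTableError(
                f"bad header {reader.fieldnames!r}; expected {CSV_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                units = Units(row["units"])
                records.append(
                    ToxRecord(
                        smiles=row["smiles"],
                        endpoint_id=row["endpoint_id"],
                        value=float(row["value"]),
                        units=units,
                        source_id=row["source_id"],
                    )
                )
            except (ValueError, KeyError, TypeError) as err:
                bad_rows.append(lineno)
                messages.append(f"line {lineno}: {err}")
    if bad_rows:
        raise RecordTableError(
            "invalid rows: " + "; ".join(messages), rows=bad_rows
        )
    return records


def write_records(path: str | Path, records: Iterable[ToxRecord]) -> None:
    """Write records as CSV; round-trips exactly through :func:`read_records`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in records:
            writer.writerow(
                [rec.smiles, rec.endpoint_id, repr(rec.value), rec.units.value, rec.source_id]
            )
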