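"""Collapse multi-source toxicity records into one value per molecule.

The same compound is frequently reported by several databases, sometimes in
different dose units and sometimes with outright disagreement.  Two
aggregation rules are implemented:

* **classification** — group records by canonical structure; if any two
  records for a molecule disagree on the binary label the molecule is
  excluded entirely, otherwise the duplicates collapse to a single entry.
* **regression** — convert every value to the endpoint's canonical scale
  (default log10 of the dose in mmol/kg), then average in two levels: first
  within each source, then an unweighted mean across the per-source means.

The two-level mean equals the plain mean whenever each source contributes a
single record, but protects against one source dominating through sheer
record count.

Molar mass for mg/kg ↔ mmol/kg conversion is computed from the structure
(average molecular weight), so no molar-mass column is needed in the input.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors

from .molio import EndpointSpec, Task, ToxRecord, Units

__all__ = [
    "CuratedDataset",
    "CuratedEntry",
    "convert_value",
    "molar_mass",
    "dedup_classification",
    "aggregate_regression",
]


@dataclass(frozen=True)
class CuratedEntry:
    canonical_smiles: str
    value: float
    n_sources: int


@dataclass
class CuratedDataset:
    """Deduplicated, unit-normalized records for one endpoint.

    Canonical SMILES are pairwise distinct; classification values are 0/1,
    regression values are finite on the endpoint's canonical scale.
    """

    endpoint: EndpointSpec
    entries: list[CuratedEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        smiles = [e.canonical_smiles for e in self.entries]
        if len(smiles) != len(set(smiles)):
            raise ValueError("canonical_smiles must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def smiles(self) -> list[str]:
        return [e.canonical_smiles for e in self.entries]

    @property
    def values(self) -> list[float]:
        return [e.value for e in self.entries]


def molar_mass(smiles: str) -> float:
    """Average molecular weight (g/mol) of a parseable SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Descriptors.MolWt(mol)


# Dose-unit conversion pivots through the linear mmol/kg scale.
_DOSE_UNITS = (Units.MG_PER_KG, Units.MMOL_PER_KG, Units.LOG10_MMOL_PER_KG)


def convert_value(
    value: float,
    from_units: Units,
    to_units: Units,
    molar_mass: float | None = None,
) -> float:
    """Convert a dose between mg/kg, mmol/kg and log10(mmol/kg).

    ``molar_mass`` (g/mol, > 0) is required only when mg/kg is involved.
    Converting to the same units is the identity; conversions compose.
    A non-positive dose cannot be put on the log scale.
    """
    if from_units not in _DOSE_UNITS or to_units not in _DOSE_UNITS:
        raise ValueError("convert_value handles dose units only, not binary")
    if from_units == to_units:
        return value
    needs_mass = Units.MG_PER_KG in (from_units, to_units)
    if needs_mass:
        if molar_mass is None or not molar_mass > 0:
            raise ValueError("molar_mass > 0 required for mg/kg conversions")

    # to linear mmol/kg
    if from_units == Units.MG_PER_KG:
        linear = value / molar_mass
    elif from_units == Units.LOG10_MMOL_PER_KG:
        linear = 10.0 ** value
    else:
        linear = value

    if to_units == Units.MMOL_PER_KG:
        return linear
    if to_units == Units.MG_PER_KG:
        return linear * molar_mass
    if linear <= 0:
        raise ValueError(f"non-positive dose {linear!r} has no log10 value")
    return math.log10(linear)


def _group_by_smiles(
    records: Iterable[ToxRecord],
) -> dict[str, list[ToxRecord]]:
    groups: dict[str, list[ToxRecord]] = defaultdict(list)
    for rec in records:
        groups[rec.smiles].append(rec)
    return groups


def dedup_classification(
    records: Sequence[ToxRecord], endpoint: EndpointSpec
) -> CuratedDataset:
    """Collapse binary-label records; exclude molecules with label conflicts.

    If any two records for a molecule disagree on the label — across or
    within sources — the molecule is excluded entirely.  Agreement collapses
    to one entry with the shared label and ``n_sources`` = number of
    distinct sources.  Entry order follows first appearance in the input.
    """
    if endpoint.task != Task.CLASSIFICATION:
        raise ValueError("endpoint must be a classification endpoint")
    for rec in records:
        if rec.units != Units.BINARY:
            raise ValueError(
                f"non-binary record for classification endpoint: {rec!r}"
            )
    entries: list[CuratedEntry] = []
    for smi, group in _group_by_smiles(records).items():
        labels = {rec.value for rec in group}
        if len(labels) > 1:
            continue  # conflicting activity: drop the molecule
        n_sources = len({rec.source_id for rec in group})
        entries.append(CuratedEntry(smi, labels.pop(), n_sources))
    return CuratedDataset(endpoint, entries)


def aggregate_regression(
    records: Sequence[ToxRecord], endpoint: EndpointSpec
) -> CuratedDataset:
    """Two-level mean aggregation of dose records on the canonical scale.

    Every value is converted to ``endpoint.canonical_units`` first, then per
    molecule: mean within each source, then an unweighted mean of the
    per-source means.  Invariant to record order and source relabeling.
    """
    if endpoint.task != Task.REGRESSION:
        raise ValueError("endpoint must be a regression endpoint")
    entries: list[CuratedEntry] = []
    mass_cache: dict[str, float] = {}
    for smi, group in _group_by_smiles(records).items():
        per_source: dict[str, list[float]] = defaultdict(list)
        for rec in group:
            if rec.units == Units.BINARY:
                raise ValueError(f"binary record in regression input: {rec!r}")
            if Units.MG_PER_KG in (rec.units, endpoint.canonical_units):
                if smi not in mass_cache:
                    mass_cache[smi] = molar_mass(smi)
                mass = mass_cache[smi]
            else:
                mass = None
            per_source[rec.source_id].append(
                convert_value(rec.value, rec.units, endpoint.canonical_units, mass)
            )
        source_means = [sum(v) / len(v) for v in per_source.values()]
        entries.append(
            CuratedEntry(smi, sum(source_means) / len(source_means), len(per_source))
        )
    return CuratedDataset(endpoint, entries)
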