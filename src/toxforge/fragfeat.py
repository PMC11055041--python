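"""Fragment-count features with an occurrence/correlation filtering cascade.

The featurization pipeline is:

1. ``count_fragments`` — molecules × fragments matrix of substructure match
   counts (symmetry-deduplicated matches).
2. ``filter_rare`` — drop fragments present (count > 0) in fewer than
   ``tau_rare`` of the molecules (default 1%; exactly at the threshold is
   kept — the rule is "less than").
3. ``filter_low_total`` — drop fragments whose total occurrence count summed
   over molecules is below ``tau_total`` × n_molecules (default 2.5%,
   i.e. mean count per molecule < 0.025; equality is kept).
4. ``prune_correlated`` — eliminate fragments until no retained pair has
   Pearson |r| > ``r_max`` (default 0.85).  Constant columns are removed
   first (their correlation is undefined); then a deterministic greedy scan
   in catalog order drops, for each offending pair, the column with the
   smaller total occurrence (tie → the later catalog index).
5. Horizontal join with whole-molecule descriptors kept when their non-zero
   frequency is ≥ ``descriptor_min_nonzero`` (default 2.5%; equality kept —
   the rule is "greater than or equal").

Stage order is fixed (rare → total → correlation) and every stage logs what
it removed and why into a :class:`FilterReport`, so feature provenance is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .catalog import FragmentCatalog, default_catalog

__all__ = [
    "FilterConfig",
    "FilterReport",
    "RemovedFeature",
    "EmptyFeatureSetError",
    "count_fragments",
    "filter_rare",
    "filter_low_total",
    "prune_correlated",
    "compute_descriptors",
    "select_descriptors",
    "featurize",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering cascade; all fractions in (0, 1]."""

    tau_rare: float = 0.01
    tau_total: float = 0.025
    r_max: float = 0.85
    descriptor_min_nonzero: float = 0.025

    def __post_init__(self) -> None:
        for name in ("tau_rare", "tau_total", "r_max", "descriptor_min_nonzero"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")


@dataclass(frozen=True)
class RemovedFeature:
    feature: str
    reason: str
    statistic: float


@dataclass
class FilterReport:
    """Per-stage record of removed features; stages are disjoint."""

    stages: dict[str, list[RemovedFeature]] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)

    def add_stage(self, name: str, removed: list[RemovedFeature]) -> None:
        if name in self.stages:
            raise ValueError(f"duplicate stage {name!r}")
        self.stages[name] = removed

    def removed_names(self) -> list[str]:
        return [r.feature for stage in self.stages.values() for r in stage]


class EmptyFeatureSetError(ValueError):
    pass


def count_fragments(
    smiles_list: Sequence[str], catalog: FragmentCatalog
) -> pd.DataFrame:
    """Molecules × fragments matrix of substructure match counts.

    Cell (i, j) is the number of distinct (symmetry-deduplicated) matches of
    pattern j in molecule i.  A pattern that fails to compile raises a
    ``ValueError`` naming the fragment_id.
    """
    queries = []
    for entry in catalog:
        q = Chem.MolFromSmarts(entry.pattern)
        if q is None:
            raise ValueError(
                f"pattern for fragment {entry.fragment_id!r} failed to "
                f"compile: {entry.pattern!r}"
            )
        queries.append((entry.fragment_id, q))
    counts = np.zeros((len(smiles_list), len(queries)), dtype=np.int64)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        for j, (_, q) in enumerate(queries):
            counts[i, j] = len(mol.GetSubstructMatches(q, uniquify=True))
    return pd.DataFrame(
        counts, index=list(smiles_list), columns=[fid for fid, _ in queries]
    )


def filter_rare(
    matrix: pd.DataFrame, tau_rare: float = 0.01
) -> tuple[pd.DataFrame, list[RemovedFeature]]:
    """Drop fragments whose binary occurrence frequency is < ``tau_rare``."""
    freq = (matrix > 0).mean(axis=0)
    removed = [
        RemovedFeature(col, f"occurrence_frequency<{tau_rare}", float(freq[col]))
        for col in matrix.columns
        if freq[col] < tau_rare
    ]
    kept = [c for c in matrix.columns if freq[c] >= tau_rare]
    return matrix[kept], removed


def filter_low_total(
    matrix: pd.DataFrame, tau_total: float = 0.025
) -> tuple[pd.DataFrame, list[RemovedFeature]]:
    """Drop fragments with total count < ``tau_total`` × n_molecules.

    The threshold makes a raw occurrence count comparable to a percentage:
    it is equivalent to requiring a mean count of at least ``tau_total`` per
    molecule.  Equality is kept.
    """
    threshold = tau_total * len(matrix)
    totals = matrix.sum(axis=0)
    removed = [
        RemovedFeature(col, f"total_occurrences<{threshold:g}", float(totals[col]))
        for col in matrix.columns
        if totals[col] < threshold
    ]
    kept = [c for c in matrix.columns if totals[c] >= threshold]
    return matrix[kept], removed


def prune_correlated(
    matrix: pd.DataFrame, r_max: float = 0.85
) -> tuple[pd.DataFrame, list[RemovedFeature]]:
    """Eliminate columns until no retained pair has Pearson |r| > ``r_max``.

    Deterministic: constant columns go first, then a greedy scan over column
    pairs in catalog order drops the member with the smaller total
    occurrence (tie → the later column).
    """
    removed: list[RemovedFeature] = []
    totals = matrix.sum(axis=0)
    is_const = matrix.nunique(axis=0) <= 1
    removed += [
        RemovedFeature(col, "constant_column", float(totals[col]))
        for col in matrix.columns
        if is_const[col]
    ]
    cols = [c for c in matrix.columns if not is_const[c]]
    sub = matrix[cols]
    if len(sub) < 2:
        raise ValueError("correlation pruning needs at least 2 molecules")
    if cols:
        corr = np.corrcoef(sub.to_numpy(dtype=float), rowvar=False)
        corr = np.atleast_2d(corr)
        alive = {c: True for c in cols}
        for i in range(len(cols)):
            if not alive[cols[i]]:
                continue
            for j in range(i + 1, len(cols)):
                ci, cj = cols[i], cols[j]
                if not alive[cj]:
                    continue
                r = corr[i, j]
                if abs(r) > r_max:
                    # drop the less frequent column; tie → later catalog index
                    drop = ci if totals[ci] < totals[cj] else cj
                    alive[drop] = False
                    removed.append(
                        RemovedFeature(drop, f"|pearson_r|>{r_max:g}", float(r))
                    )
                    if drop == ci:
                        break
        cols = [c for c in cols if alive[c]]
    return matrix[cols], removed


# Whole-molecule descriptor families: element occurrences, heavy-atom and
# bond-type counts, valence electrons, rotatable bonds, TPSA, logP,
# LabuteASA, Kappa shape indices, and the SlogP/SMR/EState VSA bins.
_SIMPLE_DESCRIPTORS = [
    ("valence_electrons", Descriptors.NumValenceElectrons),
    ("rotatable_bonds", Descriptors.NumRotatableBonds),
    ("tpsa", Descriptors.TPSA),
    ("logp", Descriptors.MolLogP),
    ("labute_asa", Descriptors.LabuteASA),
    ("kappa1", Descriptors.Kappa1),
    ("kappa2", Descriptors.Kappa2),
    ("kappa3", Descriptors.Kappa3),
]
_VSA_DESCRIPTORS = (
    [f"SlogP_VSA{i}" for i in range(1, 13)]
    + [f"SMR_VSA{i}" for i in range(1, 11)]
    + [f"EState_VSA{i}" for i in range(1, 12)]
)

_BOND_TYPES = {
    "bonds_single": Chem.BondType.SINGLE,
    "bonds_double": Chem.BondType.DOUBLE,
    "bonds_triple": Chem.BondType.TRIPLE,
    "bonds_aromatic": Chem.BondType.AROMATIC,
}


def compute_descriptors(smiles_list: Sequence[str]) -> pd.DataFrame:
    """Whole-molecule descriptor matrix for a molecule set.

    Element-occurrence columns (``elem_<symbol>``) cover the union of
    elements observed in the set, in alphabetical order.
    """
    mols = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        mols.append(mol)
    elements = sorted({a.GetSymbol() for mol in mols for a in mol.GetAtoms()})
    rows = []
    for mol in mols:
        row: dict[str, float] = {}
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        for el in elements:
            row[f"elem_{el}"] = symbols.count(el)
        row["heavy_atoms"] = mol.GetNumHeavyAtoms()
        bond_types = [b.GetBondType() for b in mol.GetBonds()]
        for name, bt in _BOND_TYPES.items():
            row[name] = bond_types.count(bt)
        for name, fn in _SIMPLE_DESCRIPTORS:
            row[name] = fn(mol)
        for name in _VSA_DESCRIPTORS:
            row[name] = getattr(Descriptors, name)(mol)
        rows.append(row)
    return pd.DataFrame(rows, index=list(smiles_list))


def select_descriptors(
    matrix: pd.DataFrame, min_nonzero: float = 0.025
) -> tuple[pd.DataFrame, list[RemovedFeature]]:
    """Keep descriptors whose non-zero frequency is ≥ ``min_nonzero``."""
    freq = (matrix != 0).mean(axis=0)
    removed = [
        RemovedFeature(col, f"nonzero_frequency<{min_nonzero}", float(freq[col]))
        for col in matrix.columns
        if freq[col] < min_nonzero
    ]
    kept = [c for c in matrix.columns if freq[c] >= min_nonzero]
    return matrix[kept], removed


def featurize(
    smiles_list: Sequence[str],
    catalog: FragmentCatalog | None = None,
    config: FilterConfig = FilterConfig(),
    include_descriptors: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full featurization: counts → rare → total → correlation → descriptors.

    Returns the joined feature matrix (fragment counts first, descriptors
    after) and the concatenated stage report.  If every fragment is
    filtered out an :class:`EmptyFeatureSetError` advises relaxing the
    thresholds.
    """
    if catalog is None:
        catalog = default_catalog()
    report = FilterReport()
    counts = count_fragments(smiles_list, catalog)
    counts, removed = filter_rare(counts, config.tau_rare)
    report.add_stage("rare", removed)
    counts, removed = filter_low_total(counts, config.tau_total)
    report.add_stage("low_total", removed)
    counts, removed = prune_correlated(counts, config.r_max)
    report.add_stage("correlated", removed)
    if counts.shape[1] == 0:
        raise EmptyFeatureSetError(
            "every fragment was filtered out; relax tau_rare/tau_total/r_max"
        )
    if include_descriptors:
        desc = compute_descriptors(smiles_list)
        desc, removed = select_descriptors(desc, config.descriptor_min_nonzero)
        report.add_stage("descriptors", removed)
        features = pd.concat([counts, desc], axis=1)
    else:
        features = counts
    report.retained = list(features.columns)
    return features, report
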