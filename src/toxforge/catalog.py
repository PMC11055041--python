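"""Substructure catalogs for fragment-count featurization.

Toxicity is frequently driven by specific functional groups or fragments —
structural alerts whose metabolism or direct reactivity produces the adverse
effect (epoxides, Michael acceptors, nitroaromatics, organophosphates, ...).
The default catalog is therefore a curated library of toxicophore-oriented
functional-group SMARTS patterns.  It can be augmented with circular atom
environments of radius 1–2 enumerated from a training set, deduplicated by
canonical SMILES, which adapts the vocabulary to the chemistry actually
present in the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from rdkit import Chem

__all__ = [
    "Provenance",
    "CatalogEntry",
    "FragmentCatalog",
    "default_catalog",
    "enumerate_environments",
]


class Provenance(str, Enum):
    FUNCTIONAL_GROUP_LIBRARY = "functional_group_library"
    ENVIRONMENT_ENUMERATION = "environment_enumeration"


@dataclass(frozen=True)
class CatalogEntry:
    fragment_id: str
    pattern: str  # SMARTS (or SMILES used as a substructure query)
    provenance: Provenance


@dataclass
class FragmentCatalog:
    """Ordered list of named substructure patterns.

    Fragment ids are unique and the order is stable across runs given the
    same inputs, so downstream filtering is deterministic.
    """

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        ids = [e.fragment_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("fragment_ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def fragment_ids(self) -> list[str]:
        return [e.fragment_id for e in self.entries]

    def extend(self, other: "FragmentCatalog") -> "FragmentCatalog":
        return FragmentCatalog(self.entries + other.entries)


# Toxicophore-oriented functional-group library.  Grouped loosely by
# chemistry; ids name the group, patterns are standard SMARTS.
FUNCTIONAL_GROUPS: list[tuple[str, str]] = [
    # oxygen
    ("hydroxyl_aliphatic", "[CX4][OX2H]"),
    ("phenol", "c[OX2H]"),
    ("catechol", "[OX2H]c1ccccc1[OX2H]"),
    ("methoxy", "[OX2][CH3]"),
    ("ether", "[OD2]([#6])[#6]"),
    ("peroxide", "[OX2][OX2]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("ester", "[CX3](=O)[OX2H0][#6]"),
    ("anhydride", "[CX3](=O)[OX2][CX3](=O)"),
    ("acyl_halide", "[CX3](=O)[F,Cl,Br,I]"),
    ("carbonate", "[OX2][CX3](=O)[OX2]"),
    ("quinone", "O=C1C=CC(=O)C=C1"),
    ("epoxide", "C1OC1"),
    # nitrogen
    ("primary_amine", "[NX3;H2;!$(NC=O);!$(N=*)]"),
    ("secondary_amine", "[NX3;H1;!$(NC=O);!$(N=*)]"),
    ("tertiary_amine", "[NX3;H0;!$(NC=O);!$(N=*);!$([N+])]"),
    ("aniline", "c[NX3;H2,H1]"),
    ("nitro", "[NX3+](=O)[O-]"),
    ("nitroaromatic", "c[NX3+](=O)[O-]"),
    ("nitroso", "[NX2]=[OX1]"),
    ("n_nitroso", "[NX3][NX2]=[OX1]"),
    ("nitrate_ester", "[OX2][NX3+](=O)[O-]"),
    ("azo", "[#6]N=N[#6]"),
    ("azide", "[NX2]=[NX2+]=[NX1-]"),
    ("nitrile", "[CX2]#[NX1]"),
    ("isocyanate", "[NX2]=[CX2]=[OX1]"),
    ("isothiocyanate", "[NX2]=[CX2]=[SX1]"),
    ("amide", "[CX3](=O)[NX3]"),
    ("carbamate", "[NX3][CX3](=O)[OX2H0]"),
    ("urea", "[NX3][CX3](=O)[NX3]"),
    ("thiourea", "[NX3][CX3](=S)[NX3]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("hydrazine", "[NX3][NX3]"),
    ("hydrazone", "[CX3]=[NX2][NX3]"),
    ("oxime", "[CX3]=[NX2][OX2H]"),
    ("imine", "[CX3]=[NX2]"),
    ("n_oxide", "[#7+][O-]"),
    ("quaternary_ammonium", "[NX4+]"),
    ("aziridine", "C1NC1"),
    # sulfur / phosphorus
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("disulfide", "[SX2][SX2]"),
    ("sulfoxide", "[#16X3]=[OX1]"),
    ("sulfone", "[#16X4](=[OX1])(=[OX1])"),
    ("sulfonamide", "[#16X4](=[OX1])(=[OX1])[NX3]"),
    ("sulfonate_ester", "[#16X4](=[OX1])(=[OX1])[OX2][#6]"),
    ("thiocarbonyl", "[CX3]=[SX1]"),
    ("phosphoryl", "[PX4]=[OX1]"),
    ("thiophosphoryl", "[PX4]=[SX1]"),
    ("phosphate_ester", "[PX4](=[OX1])([OX2])[OX2]"),
    # halogens and reactive carbon
    ("aryl_halide", "c[F,Cl,Br,I]"),
    ("alkyl_halide", "[CX4][F,Cl,Br,I]"),
    ("trifluoromethyl", "[CX4](F)(F)F"),
    ("alpha_halo_carbonyl", "[F,Cl,Br,I][CX4][CX3]=O"),
    ("michael_acceptor", "[CX3]=[CX3][CX3]=[OX1]"),
    ("vinyl", "[CX3]=[CX2H2]"),
    ("alkene", "[CX3]=[CX3]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("allyl_halide", "[CX3]=[CX3][CX4][F,Cl,Br,I]"),
    # rings
    ("benzene", "c1ccccc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("biphenyl", "c1ccc(-c2ccccc2)cc1"),
    ("pyridine", "c1ccncc1"),
    ("pyrimidine", "c1cncnc1"),
    ("furan", "c1ccoc1"),
    ("thiophene", "c1ccsc1"),
    ("pyrrole", "c1cc[nH]c1"),
    ("imidazole", "c1c[nH]cn1"),
    ("piperidine", "C1CCNCC1"),
    ("piperazine", "C1CNCCN1"),
    ("morpholine", "C1COCCN1"),
    ("tetrahydrofuran", "C1CCOC1"),
    ("cyclopropane", "C1CC1"),
    ("cyclohexane", "C1CCCCC1"),
    # whitelist metalloids
    ("boron_any", "[B]"),
    ("silicon_any", "[Si]"),
    ("arsenic_any", "[As]"),
    ("selenium_any", "[Se]"),
]


def default_catalog() -> FragmentCatalog:
    """The curated functional-group library as a catalog."""
    entries = [
        CatalogEntry(name, smarts, Provenance.FUNCTIONAL_GROUP_LIBRARY)
        for name, smarts in FUNCTIONAL_GROUPS
    ]
    return FragmentCatalog(entries)


def enumerate_environments(
    smiles_list: Sequence[str], radii: Iterable[int] = (1, 2)
) -> FragmentCatalog:
    """Enumerate circular atom environments from a molecule set.

    For every atom in every molecule and every radius in ``radii``, the bond
    environment is extracted and written as canonical SMILES; duplicates are
    merged.  The catalog is sorted by (radius, pattern) so the result is a
    pure function of the input set, independent of molecule order.
    """
    seen: dict[tuple[int, str], None] = {}
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        for radius in radii:
            for atom in mol.GetAtoms():
                env = Chem.FindAtomEnvironmentOfRadiusN(
                    mol, radius, atom.GetIdx()
                )
                if not env:
                    continue
                submol = Chem.PathToSubmol(mol, env)
                if submol.GetNumAtoms() == 0:
                    continue
                frag = Chem.MolToSmiles(submol)
                if frag:
                    seen.setdefault((radius, frag))
    entries = [
        CatalogEntry(
            f"env_r{radius}_{i:04d}", frag, Provenance.ENVIRONMENT_ENUMERATION
        )
        for i, (radius, frag) in enumerate(sorted(seen))
    ]
    return FragmentCatalog(entries)
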