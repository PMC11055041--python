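"""Synthetic multi-source toxicity data with known ground truth.

Real toxicity databases overlap: the same compound is reported by several
sources, in different dose units, with per-source noise and occasional
outright label conflicts.  The generators here emulate exactly that
structure — so every curation stage (canonicalization, element filtering,
conflict exclusion, two-level averaging, fragment featurization) can be
tested against a planted truth without downloading anything.

Molecules are built by template substitution (scaffold × substituents, all
drawn from the 13-element curation whitelist), which guarantees chemical
validity without a generative model.  An optional decoy fraction spikes in
whitelist-violating and carbon-free structures for filter tests.  Latent
toxicity is drawn on the log10(mmol/kg) scale and can be shifted linearly
by the count of a planted fragment, the simplest mechanism under which
fragment features are provably informative.

Every generator output is a pure function of its configuration, including
the seed.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .aggregate import molar_mass
from .modelkit import MetricTable
from .molio import ToxRecord, Units, canonicalize

__all__ = [
    "SyntheticConfig",
    "gen_molecules",
    "gen_regression_records",
    "gen_classification_records",
    "expected_exclusion_fraction",
    "load_paper_tables",
    "DECOYS",
]

# Scaffolds with carbon substitution slots, and single-bond substituents.
# The product space (deduplicated by canonical SMILES) is ~2000 molecules.
_SCAFFOLDS_1 = [
    "c1ccc({a})cc1",
    "c1ccnc({a})c1",
    "c1coc({a})c1",
    "c1csc({a})c1",
    "C1CCC({a})CC1",
]
_SCAFFOLDS_2 = [
    "c1ccc({a})c({b})c1",
    "c1cc({a})ccc1{b}",
    "CC({a})C{b}",
    "C({a})CC{b}",
]
_SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "O", "OC", "N", "NC", "N(C)C",
    "Cl", "Br", "F", "I", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)OC",
    "C(=O)N", "[N+](=O)[O-]", "S", "SC", "C=C", "CO", "C=O",
]

#: Structures the element filter must reject: carbon-free acids and
#: organometallics with non-whitelisted elements.
DECOYS = [
    "O=S(=O)(O)O",
    "OP(=O)(O)O",
    "O=[N+]([O-])O",
    "NN",
    "CC[Hg]CC",
    "C[Sn](C)(C)C",
    "CC[Pb](CC)CC",
    "C[Ge](C)(C)C",
]


@functools.lru_cache(maxsize=1)
def _molecule_space() -> tuple[str, ...]:
    """All canonical template-substitution products, sorted (deterministic)."""
    seen: set[str] = set()
    for scaffold in _SCAFFOLDS_1:
        for a in _SUBSTITUENTS:
            seen.add(canonicalize(scaffold.format(a=a)))
    for scaffold in _SCAFFOLDS_2:
        for a in _SUBSTITUENTS:
            for b in _SUBSTITUENTS:
                seen.add(canonicalize(scaffold.format(a=a, b=b)))
    return tuple(sorted(seen))


def gen_molecules(
    n: int, seed: int, decoy_fraction: float = 0.0
) -> list[str]:
    """``n`` canonical SMILES, deterministic per seed.

    A ``decoy_fraction`` of the output (rounded to the nearest count) is
    drawn from :data:`DECOYS` — structures the element filter removes —
    interleaved at seeded positions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_decoys = int(round(decoy_fraction * n))
    n_real = n - n_decoys
    space = _molecule_space()
    if n_real > len(space):
        raise ValueError(
            f"template space holds {len(space)} molecules, asked for {n_real}"
        )
    real = list(rng.permutation(space)[:n_real])
    decoys = [canonicalize(DECOYS[i % len(DECOYS)]) for i in range(n_decoys)]
    out = real + decoys
    rng.shuffle(out)
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of a synthetic multi-source record set.

    ``duplicate_rate`` is the probability a molecule is reported by more
    than one source (the number of reporting sources is then uniform on
    {2..n_sources}); ``conflict_rate`` is the per-extra-source label-flip
    probability for classification; ``noise_sd`` is the per-source additive
    noise (log10 units) for regression; ``unit_mix`` gives the fractions of
    records expressed in each dose unit.
    """

    n_molecules: int = 500
    n_sources: int = 3
    duplicate_rate: float = 0.3
    conflict_rate: float = 0.1
    noise_sd: float = 0.3
    unit_mix: tuple[tuple[Units, float], ...] = (
        (Units.LOG10_MMOL_PER_KG, 0.5),
        (Units.MMOL_PER_KG, 0.3),
        (Units.MG_PER_KG, 0.2),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        for name in ("duplicate_rate", "conflict_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(f for _, f in self.unit_mix) - 1.0) > 1e-9:
            raise ValueError("unit_mix fractions must sum to 1")


# Latent log10(mmol/kg) population: centred near 0.5 with unit spread,
# matching the order of magnitude of rodent LD50 datasets.
_LATENT_MEAN = 0.5
_LATENT_SD = 1.0


def _sources_for_molecule(rng: np.random.Generator, cfg: SyntheticConfig):
    if cfg.n_sources > 1 and rng.random() < cfg.duplicate_rate:
        k = int(rng.integers(2, cfg.n_sources + 1))
    else:
        k = 1
    return rng.choice(cfg.n_sources, size=k, replace=False)


def _pick_units(rng: np.random.Generator, cfg: SyntheticConfig) -> Units:
    units = [u for u, _ in cfg.unit_mix]
    probs = [f for _, f in cfg.unit_mix]
    return units[rng.choice(len(units), p=probs)]


def gen_regression_records(
    cfg: SyntheticConfig,
    endpoint_id: str = "ld50_synthetic",
    planted_smarts: str | None = None,
    planted_effect: float = 0.0,
) -> tuple[list[ToxRecord], dict[str, float]]:
    """Multi-source dose records around a latent log-dose per molecule.

    Each molecule receives a latent value ~ N(0.5, 1) on log10(mmol/kg);
    each reporting source observes latent + N(0, noise_sd), re-expressed in
    a unit drawn from ``unit_mix`` (mg/kg via the molecule's molar mass).
    With ``planted_smarts`` the latent value is shifted by
    ``planted_effect`` × (count of that fragment), planting a toxicophore
    signal.  Returns the records and the molecule → latent truth map.
    """
    from rdkit import Chem

    rng = np.random.default_rng(cfg.seed)
    molecules = gen_molecules(cfg.n_molecules, cfg.seed)
    query = None
    if planted_smarts is not None:
        query = Chem.MolFromSmarts(planted_smarts)
        if query is None:
            raise ValueError(f"bad planted SMARTS: {planted_smarts!r}")
    records: list[ToxRecord] = []
    truth: dict[str, float] = {}
    for smi in molecules:
        latent = _LATENT_MEAN + _LATENT_SD * rng.standard_normal()
        if query is not None:
            mol = Chem.MolFromSmiles(smi)
            latent += planted_effect * len(
                mol.GetSubstructMatches(query, uniquify=True)
            )
        truth[smi] = latent
        for src in _sources_for_molecule(rng, cfg):
            obs = latent + cfg.noise_sd * rng.standard_normal()
            units = _pick_units(rng, cfg)
            if units == Units.LOG10_MMOL_PER_KG:
                value = obs
            elif units == Units.MMOL_PER_KG:
                value = 10.0 ** obs
            else:
                value = (10.0 ** obs) * molar_mass(smi)
            records.append(
                ToxRecord(smi, endpoint_id, value, units, f"src{src}")
            )
    return records, truth


def gen_classification_records(
    cfg: SyntheticConfig, endpoint_id: str = "tox_binary_synthetic"
) -> tuple[list[ToxRecord], dict[str, int]]:
    """Multi-source binary records with label conflicts at a known rate.

    Each molecule gets a true Bernoulli(1/2) label; its first source
    reports it faithfully, every additional source flips it independently
    with probability ``conflict_rate`` — producing the cross-source
    mismatch condition at the analytically known rate of
    :func:`expected_exclusion_fraction`.
    """
    rng = np.random.default_rng(cfg.seed)
    molecules = gen_molecules(cfg.n_molecules, cfg.seed)
    records: list[ToxRecord] = []
    truth: dict[str, int] = {}
    for smi in molecules:
        label = int(rng.random() < 0.5)
        truth[smi] = label
        sources = _sources_for_molecule(rng, cfg)
        for i, src in enumerate(sources):
            reported = label
            if i > 0 and rng.random() < cfg.conflict_rate:
                reported = 1 - reported
            records.append(
                ToxRecord(
                    smi, endpoint_id, float(reported), Units.BINARY, f"src{src}"
                )
            )
    return records, truth


def expected_exclusion_fraction(cfg: SyntheticConfig) -> float:
    """Closed-form probability a molecule is excluded by conflict dedup.

    A molecule reported by k sources survives iff none of its k−1 extra
    sources flips; k is uniform on {2..n_sources} for the duplicated
    fraction, so

        P(excluded) = duplicate_rate · mean_k [1 − (1 − c)^(k−1)].
    """
    if cfg.n_sources < 2:
        return 0.0
    c = cfg.conflict_rate
    ks = range(2, cfg.n_sources + 1)
    per_k = [1.0 - (1.0 - c) ** (k - 1) for k in ks]
    return cfg.duplicate_rate * float(np.mean(per_k))


def load_paper_tables() -> tuple[MetricTable, MetricTable]:
    """The shipped benchmark tables: (regression 29 rows, classification 22).

    Per-target five-fold CV metrics for the fingerprint CatBoost and
    fragment XGBoost models against published/website benchmarks, with
    sample counts, transcribed verbatim.
    """
    data = resources.files("toxforge") / "data"
    with resources.as_file(data / "table4_regression.csv") as p:
        regression = MetricTable.from_csv(p)
    with resources.as_file(data / "table5_classification.csv") as p:
        classification = MetricTable.from_csv(p)
    return regression, classification
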