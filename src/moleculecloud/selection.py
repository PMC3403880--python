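"""Turn raw substructure frequencies into the display set.

Scaffold frequencies in chemical databases follow a long-tail power law: a
handful of cores (benzene above all) dominate, and roughly half of all
scaffolds are singletons.  Three consequences shape this module: ubiquitous
stop-structures (benzene by default) are removed, like stop words in a text
cloud; only the top N most frequent cores are displayed (100-250 reads
well at screen size); and image magnification is interpolated linearly in
*log* frequency between a configurable minimum and maximum, since raw
counts would make the head of the distribution unreadably dominant.

The module also hosts the synthetic fixture generators used for testing and
demonstration: they draw valid ring-system SMILES from a built-in library
and assign rank-frequency counts proportional to rank^(-exponent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .substructure import Kind, MoleculeInput, SubstructureRecord, canonicalize

__all__ = [
    "CloudSpec",
    "select_top",
    "scale_factor",
    "scale_records",
    "generate_powerlaw_fixture",
    "generate_molecule_fixture",
    "SCAFFOLD_LIBRARY",
    "TARGET_CLASSES",
]

BENZENE = "c1ccccc1"


@dataclass(frozen=True)
class CloudSpec:
    """Selection, scaling and coloring configuration for one cloud.

    ``min_scale``/``max_scale`` multiply each structure's natural depiction
    size; the defaults (1.0-3.5) make the 30-50 most frequent cores easily
    recognizable while the rest fill the background.
    """

    top_n: int = 200
    min_scale: float = 1.0
    max_scale: float = 3.5
    stop_structures: tuple[str, ...] = (BENZENE,)
    drop_singletons: bool = False
    color_scheme: str = "none"  # none | activity_intensity | target_class

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (0 < self.min_scale < self.max_scale):
            raise ValueError("need 0 < min_scale < max_scale")
        if self.color_scheme not in ("none", "activity_intensity", "target_class"):
            raise ValueError(f"unknown color_scheme {self.color_scheme!r}")


@dataclass
class SelectionCounts:
    """Bookkeeping for the run report."""

    input_records: int = 0
    stop_removed: int = 0
    singleton_removed: int = 0
    below_top_n: int = 0
    displayed: int = 0


def select_top(records: list[SubstructureRecord], spec: CloudSpec,
               counts: SelectionCounts | None = None) -> list[SubstructureRecord]:
    """Drop stop-structures, sort by frequency (ties by canonical SMILES),
    keep the top N.  Raises ``ValueError`` when nothing is left to display."""
    stop = {canonicalize(s) for s in spec.stop_structures}
    if counts is not None:
        counts.input_records = len(records)
    kept = []
    for r in records:
        if r.canonical_smiles in stop:
            if counts is not None:
                counts.stop_removed += 1
        elif spec.drop_singletons and r.frequency == 1:
            if counts is not None:
                counts.singleton_removed += 1
        else:
            kept.append(r)
    kept.sort(key=lambda r: (-r.frequency, r.canonical_smiles))
    if counts is not None:
        counts.below_top_n = max(0, len(kept) - spec.top_n)
        counts.displayed = min(len(kept), spec.top_n)
    out = kept[:spec.top_n]
    if not out:
        raise ValueError("no displayable records (all inputs were stop-structures"
                         " or removed singletons)")
    return out


def scale_factor(frequency: int, f_min: int, f_max: int, spec: CloudSpec) -> float:
    """Magnification for a given frequency: linear interpolation in log
    frequency between ``min_scale`` (at ``f_min``) and ``max_scale`` (at
    ``f_max``); the midpoint when all frequencies are equal."""
    if f_min < 1:
        raise ValueError("f_min must be >= 1")
    if not (f_min <= frequency <= f_max):
        raise ValueError(f"frequency {frequency} outside [{f_min}, {f_max}]")
    if f_min == f_max:
        return 0.5 * (spec.min_scale + spec.max_scale)
    t = (math.log(frequency) - math.log(f_min)) / (math.log(f_max) - math.log(f_min))
    return spec.min_scale + (spec.max_scale - spec.min_scale) * t


def scale_records(records: list[SubstructureRecord], spec: CloudSpec) -> list[float]:
    """Scale factor for every record, anchored at the min/max frequency present."""
    if not records:
        return []
    freqs = [r.frequency for r in records]
    f_min, f_max = min(freqs), max(freqs)
    return [scale_factor(f, f_min, f_max, spec) for f in freqs]


# --- synthetic fixtures -----------------------------------------------------

#: Ring systems commonly seen at the head of scaffold-frequency rankings
#: (privileged cores like biphenyl, indole, quinoline and purine included).
SCAFFOLD_LIBRARY: tuple[str, ...] = (
    "c1ccccc1", "c1ccncc1", "c1ccc(-c2ccccc2)cc1", "c1ccc2[nH]ccc2c1",
    "c1ccc2ncccc2c1", "c1ncc2nc[nH]c2n1", "c1ccc2ccccc2c1", "C1CCNCC1",
    "C1CCNC1", "C1CCOC1", "C1COCCN1", "C1CNCCN1", "c1ccoc1", "c1ccsc1",
    "c1cc[nH]c1", "c1cncnc1", "c1ccnnc1", "c1cnccn1", "c1cn[nH]c1",
    "c1cnc[nH]1", "c1cscn1", "c1cocn1", "C1CCCCC1", "C1CCCC1", "C1CCCCCC1",
    "c1ccc2c(c1)CCCC2", "c1ccc2c(c1)CCC2", "c1ccc2c(c1)OCO2",
    "c1ccc2c(c1)ncs2", "c1ccc2c(c1)nc[nH]2", "c1ccc2[nH]ncc2c1",
    "c1ccc2sccc2c1", "c1ccc2occc2c1", "c1ccc2c(c1)nco2", "c1ccc2ncncc2c1",
    "c1ccc2cnccc2c1", "c1ccc(-c2ccncc2)cc1", "c1ccc(-c2nccs2)cc1",
    "c1ccc(-c2ccc3ccccc3c2)cc1", "c1ccc(N2CCNCC2)cc1", "c1ccc(N2CCOCC2)cc1",
    "c1ccc(C2CCNCC2)cc1", "O=C1CCCCC1", "O=C1CCCN1", "O=C1CCCCN1",
    "O=C1NC(=O)c2ccccc21", "O=c1cc[nH]c(=O)[nH]1", "O=c1ccocc1",
    "O=c1ccoc2ccccc12", "O=C1CCOc2ccccc21", "c1ccc2c(c1)CNCC2",
    "c1ccc2c(c1)CCCN2", "C1=CCCCC1", "C1=CCCC1", "C1CCOCC1", "C1CCSCC1",
    "c1csc2ccncc12", "c1cnn2cccc2c1", "c1cnc2[nH]ccc2c1", "c1ncc2ccsc2n1",
)

#: The six target classes used for cloud color coding.
TARGET_CLASSES: tuple[str, ...] = (
    "GPCR", "kinase", "protease", "other_enzyme", "nuclear_receptor",
    "ion_channel",
)

#: Simple side chains used to decorate fixture scaffolds; all attach by a
#: single bond and therefore never change the scaffold of the product.
_DECORATIONS: tuple[tuple[int, ...], ...] = (
    (6,), (6, 6), (8,), (7,), (6, 8), (6, 7), (6, 6, 8), (9,), (17,),
    (6, 6, 6), (8, 6), (7, 6),
)


def _compose_variant(idx: int) -> str:
    """Deterministically compose extra ring-system SMILES (ring-ring links
    with increasing linker lengths) when a fixture needs more scaffolds than
    the built-in library holds."""
    from rdkit import Chem

    n = len(SCAFFOLD_LIBRARY)
    a = SCAFFOLD_LIBRARY[idx % n]
    b = SCAFFOLD_LIBRARY[(idx // n) % n]
    # join the first atoms of each part, through a carbon linker whose length
    # grows once all direct pairings are exhausted
    ma, mb = Chem.MolFromSmiles(a), Chem.MolFromSmiles(b)
    combo = Chem.RWMol(Chem.CombineMols(ma, mb))
    prev = 0
    for _ in range(idx // (n * n)):
        c = combo.AddAtom(Chem.Atom(6))
        combo.AddBond(prev, c, Chem.BondType.SINGLE)
        prev = c
    combo.AddBond(prev, ma.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        return ""


def _scaffold_pool(n_scaffolds: int) -> list[str]:
    """Canonical, duplicate-free scaffold SMILES, extended by composed
    variants when the library is too small."""
    pool: list[str] = []
    seen: set[str] = set()
    for smi in SCAFFOLD_LIBRARY:
        can = canonicalize(smi)
        if can not in seen:
            seen.add(can)
            pool.append(can)
    idx = 0
    while len(pool) < n_scaffolds:
        smi = _compose_variant(idx)
        idx += 1
        if smi and smi not in seen:
            seen.add(smi)
            pool.append(smi)
        if idx > 100 * n_scaffolds:  # safety valve; never hit in practice
            raise RuntimeError("could not compose enough scaffold variants")
    return pool[:n_scaffolds]


def _powerlaw_counts(n_scaffolds: int, exponent: float, n_molecules: int) -> np.ndarray:
    """Integer frequencies with freq(rank) ∝ rank^(-exponent), each >= 1,
    summing exactly to ``n_molecules`` (largest-remainder rounding, then the
    residual absorbed by the top rank)."""
    if n_molecules < n_scaffolds:
        raise ValueError("n_molecules must be >= n_scaffolds so every scaffold"
                         " occurs at least once")
    ranks = np.arange(1, n_scaffolds + 1, dtype=float)
    weights = ranks ** (-exponent)
    raw = weights / weights.sum() * n_molecules
    counts = np.maximum(np.floor(raw).astype(int), 1)
    deficit = int(n_molecules - counts.sum())
    if deficit > 0:
        frac = raw - np.floor(raw)
        order = np.argsort(-frac, kind="stable")
        counts[order[:deficit % n_scaffolds]] += 1
        counts[0] += deficit - (deficit % n_scaffolds)
    elif deficit < 0:
        counts[0] += deficit  # top rank always large enough to absorb
        if counts[0] < 1:
            raise ValueError("cannot satisfy total with every frequency >= 1")
    return counts


def generate_powerlaw_fixture(n_scaffolds: int, exponent: float = 1.5,
                              n_molecules: int = 100_000, seed: int = 0,
                              annotate: str = "none",
                              ) -> list[SubstructureRecord]:
    """Synthetic aggregated scaffold records with a long-tail rank-frequency
    curve — the shape real compound collections exhibit.

    ``annotate="activity"`` adds a random activity ratio per record;
    ``annotate="target_class"`` adds class fractions in which one class
    usually dominates (so both colored and uncolored records occur).
    Deterministic for a given seed.
    """
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    rng = np.random.default_rng(seed)
    pool = _scaffold_pool(n_scaffolds)
    counts = _powerlaw_counts(n_scaffolds, exponent, n_molecules)
    records = []
    for smi, freq in zip(pool, counts):
        ratio = None
        fractions: dict[str, float] = {}
        if annotate == "activity":
            ratio = float(np.round(rng.uniform(0.0, 1.0), 3))
        elif annotate == "target_class":
            major = str(rng.choice(TARGET_CLASSES))
            share = float(rng.uniform(0.4, 1.0))
            fractions = {major: round(share, 3)}
            rest = 1.0 - share
            minor = str(rng.choice(TARGET_CLASSES))
            if minor != major and rest > 0.01:
                fractions[minor] = round(rest * float(rng.uniform(0.2, 1.0)), 3)
        records.append(SubstructureRecord(canonicalize(smi), Kind.SCAFFOLD,
                                          int(freq), ratio, fractions))
    return records


def generate_molecule_fixture(n_scaffolds: int = 150, exponent: float = 1.5,
                              n_molecules: int = 100_000, seed: int = 0,
                              annotate: str = "none",
                              variants_per_scaffold: int = 8,
                              ) -> list[MoleculeInput]:
    """A raw molecule stream whose scaffold reduction reproduces a power-law
    fixture: each scaffold is emitted ``freq`` times, decorated with random
    single-bonded side chains (which scaffold extraction removes again).

    The output order is shuffled so aggregation cannot rely on grouping.
    """
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    pool = _scaffold_pool(n_scaffolds)
    counts = _powerlaw_counts(n_scaffolds, exponent, n_molecules)
    mols: list[MoleculeInput] = []
    for s_idx, (smi, freq) in enumerate(zip(pool, counts)):
        base = Chem.MolFromSmiles(smi)
        variants = [smi]
        attempts = 0
        while len(variants) < min(int(freq), variants_per_scaffold) and attempts < 40:
            attempts += 1
            v = _decorate(base, rng)
            if v and v not in variants:
                variants.append(v)
        p_active = float(rng.uniform(0.0, 1.0))
        major = str(rng.choice(TARGET_CLASSES))
        p_major = float(rng.uniform(0.4, 1.0))
        for k in range(int(freq)):
            smiles = variants[int(rng.integers(len(variants)))]
            ann: dict[str, object] = {}
            if annotate == "activity":
                ann["is_active"] = bool(rng.uniform() < p_active)
            elif annotate == "target_class":
                if rng.uniform() < p_major:
                    ann["target_class"] = major
                else:
                    ann["target_class"] = str(rng.choice(TARGET_CLASSES))
            mols.append(MoleculeInput(smiles, name=f"s{s_idx}_m{k}",
                                      annotations=ann or None))
    perm = rng.permutation(len(mols))
    return [mols[i] for i in perm]


def _decorate(base, rng) -> str:
    """Attach one or two random single-bonded side chains to a copy of
    ``base``; returns "" when no valence allows it."""
    from rdkit import Chem

    em = Chem.RWMol(base)
    n_chains = 1 + int(rng.integers(2))
    for _ in range(n_chains):
        em.UpdatePropertyCache(strict=False)
        candidates = [a.GetIdx() for a in em.GetAtoms()
                      if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0]
        if not candidates:
            return ""
        anchor = int(candidates[int(rng.integers(len(candidates)))])
        chain = _DECORATIONS[int(rng.integers(len(_DECORATIONS)))]
        prev = anchor
        for z in chain:
            idx = em.AddAtom(Chem.Atom(int(z)))
            em.AddBond(prev, idx, Chem.BondType.SINGLE)
            prev = idx
    try:
        mol = em.GetMol()
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        return ""
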