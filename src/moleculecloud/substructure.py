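"""Reduce molecules to the substructures a cloud diagram displays.

A molecule with rings is represented by its *scaffold* (Murcko framework):
every ring atom plus every linker atom lying on a path between rings, with
all side-chain atoms removed.  By the usual Murcko convention, atoms double-
or triple-bonded directly to that framework (e.g. a ring carbonyl oxygen)
are retained; a switch disables this.  A ring-free molecule falls back to
its *major chain* — the longest simple heavy-atom path, ties broken first
by heteroatom count, then by lexicographically smallest canonical SMILES.
*Substituents* are the single-bond-attached fragments cut off a scaffold,
each marked with a dummy attachment atom.

Identical cores aggregate by canonical SMILES (stereochemistry stripped,
largest covalent fragment of salts).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")  # parse failures are reported via counts, not stderr

__all__ = [
    "Kind",
    "MoleculeInput",
    "SubstructureRecord",
    "ReductionReport",
    "parse_smiles",
    "canonicalize",
    "framework_atoms",
    "extract_scaffold",
    "extract_major_chain",
    "extract_substituents",
    "reduce_collection",
]


class Kind(str, enum.Enum):
    SCAFFOLD = "scaffold"
    CHAIN = "chain"
    SUBSTITUENT = "substituent"


@dataclass(frozen=True)
class MoleculeInput:
    """One input molecule: SMILES, optional name, optional annotations
    (``is_active``: bool, ``target_class``: str)."""

    smiles: str
    name: str | None = None
    annotations: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")


@dataclass
class SubstructureRecord:
    """An aggregated scaffold/chain/substituent with its frequency.

    ``activity_ratio`` is the fraction of contributing molecules flagged
    active (None when no activity annotations were seen); ``class_fractions``
    maps target-class labels to the fraction of contributing molecules so
    labelled.
    """

    canonical_smiles: str
    kind: Kind
    frequency: int = 1
    activity_ratio: float | None = None
    class_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")


@dataclass
class ReductionReport:
    parsed: int = 0
    failed: int = 0


def parse_smiles(smiles: str) -> Chem.Mol | None:
    """Parse SMILES; multi-fragment inputs (salts) are reduced to the largest
    covalent fragment; stereochemistry is stripped so stereoisomers aggregate."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        Chem.SanitizeMol(mol)
    Chem.RemoveStereochemistry(mol)
    return mol


def canonicalize(mol: Chem.Mol | str) -> str:
    """Canonical (aromatic, stereo-free) SMILES — the aggregation key.

    Idempotent: canonicalizing the output returns it unchanged.  Raises
    ``ValueError`` on unparseable input.
    """
    if isinstance(mol, str):
        parsed = parse_smiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    return Chem.MolToSmiles(mol)


def framework_atoms(mol: Chem.Mol, keep_exocyclic: bool = True) -> set[int]:
    """Atom indices of the scaffold: ring atoms, linker atoms, and (optionally)
    atoms multiply-bonded directly to either.

    Linkers are found by iteratively deleting non-ring atoms of degree 1;
    whatever survives alongside the rings lies on a path between ring atoms.
    """
    ring_atoms = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
    if not ring_atoms:
        return set()
    keep = set(range(mol.GetNumAtoms()))
    degree = {a.GetIdx(): a.GetDegree() for a in mol.GetAtoms()}
    changed = True
    while changed:
        changed = False
        for idx in list(keep):
            if idx in ring_atoms or degree[idx] > 1:
                continue
            keep.discard(idx)
            changed = True
            atom = mol.GetAtomWithIdx(idx)
            for nb in atom.GetNeighbors():
                if nb.GetIdx() in keep:
                    degree[nb.GetIdx()] -= 1
    if keep_exocyclic:
        extra = set()
        for bond in mol.GetBonds():
            if bond.GetBondType() == Chem.BondType.SINGLE:
                continue
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in keep and j not in keep:
                extra.add(j)
            elif j in keep and i not in keep:
                extra.add(i)
        keep |= extra
    return keep


def _submol(mol: Chem.Mol, atom_indices: set[int]) -> Chem.Mol:
    """Copy of ``mol`` restricted to ``atom_indices``.

    Stripping a substituent off a pyrrole-type aromatic nitrogen must put the
    nitrogen's hydrogen back, or the ring can no longer be kekulized.
    """
    em = Chem.RWMol(mol)
    removed = set(range(mol.GetNumAtoms())) - atom_indices
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for kept, gone in ((i, j), (j, i)):
            if kept in atom_indices and gone in removed:
                atom = em.GetAtomWithIdx(kept)
                if (atom.GetIsAromatic() and atom.GetAtomicNum() == 7
                        and atom.GetFormalCharge() == 0):
                    atom.SetNumExplicitHs(atom.GetNumExplicitHs() + 1)
    for idx in sorted(removed, reverse=True):
        em.RemoveAtom(idx)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return out


def extract_scaffold(mol: Chem.Mol, keep_exocyclic: bool = True) -> Chem.Mol | None:
    """Murcko-style framework of ``mol``; None when the molecule has no rings
    (caller falls back to :func:`extract_major_chain`)."""
    keep = framework_atoms(mol, keep_exocyclic=keep_exocyclic)
    if not keep:
        return None
    return _submol(mol, keep)


def _is_hetero(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() not in (1, 6)


def extract_major_chain(mol: Chem.Mol) -> Chem.Mol:
    """Longest simple heavy-atom path of an acyclic molecule.

    Ranking: longest path first, then most heteroatoms, then the path whose
    canonical SMILES sorts lexicographically smallest (a deterministic
    residual tie-break).  Raises ``ValueError`` on ring-containing input.
    In an acyclic graph the path between any two atoms is unique, so all
    simple paths are exactly the atom-pair paths.
    """
    if mol.GetRingInfo().NumRings() > 0:
        raise ValueError("extract_major_chain requires an acyclic molecule")
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("empty molecule")
    if n == 1:
        return Chem.Mol(mol)

    best: tuple[int, int, str] | None = None  # (-len, -het, smiles) minimized
    best_path: tuple[int, ...] | None = None
    hetero = [_is_hetero(a) for a in mol.GetAtoms()]
    for i in range(n):
        for j in range(i + 1, n):
            path = Chem.GetShortestPath(mol, i, j)
            length = len(path)
            het = sum(1 for idx in path if hetero[idx])
            if best is not None and (-length, -het) > (best[0], best[1]):
                continue
            smi = Chem.MolToSmiles(_path_submol(mol, path))
            key = (-length, -het, smi)
            if best is None or key < best:
                best = key
                best_path = path
    assert best_path is not None
    return _path_submol(mol, best_path)


def _path_submol(mol: Chem.Mol, path: Iterable[int]) -> Chem.Mol:
    return _submol(mol, set(path))


def extract_substituents(mol: Chem.Mol, max_atoms: int = 15,
                         keep_exocyclic: bool = True) -> list[str]:
    """Fragments hanging off the scaffold by a single bond, as SMILES with a
    ``*`` dummy marking the attachment point.

    Only fragments with at most ``max_atoms`` heavy atoms (the dummy not
    counted) are returned; ring-free molecules yield an empty list.
    """
    if max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")
    scaffold = framework_atoms(mol, keep_exocyclic=keep_exocyclic)
    if not scaffold:
        return []
    cut_bonds = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (i in scaffold) != (j in scaffold):
            cut_bonds.append(bond.GetIdx())
    if not cut_bonds:
        return []
    frag_mol = Chem.FragmentOnBonds(mol, cut_bonds, addDummies=True)
    out: list[str] = []
    for ids in Chem.GetMolFrags(frag_mol):
        if any(idx < mol.GetNumAtoms() and idx in scaffold for idx in ids):
            continue
        heavy = [idx for idx in ids
                 if frag_mol.GetAtomWithIdx(idx).GetAtomicNum() > 0]
        if len(heavy) > max_atoms:
            continue
        piece = _submol_raw(frag_mol, set(ids))
        for atom in piece.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetIsotope(0)  # normalize [n*] labels to plain *
        out.append(Chem.MolToSmiles(piece))
    return out


def _submol_raw(mol: Chem.Mol, atom_indices: set[int]) -> Chem.RWMol:
    em = Chem.RWMol(mol)
    for idx in sorted(set(range(mol.GetNumAtoms())) - atom_indices, reverse=True):
        em.RemoveAtom(idx)
    return em


def reduce_collection(mols: Iterable[MoleculeInput], mode: str = "scaffold",
                      keep_exocyclic: bool = True, max_substituent_atoms: int = 15,
                      ) -> tuple[list[SubstructureRecord], ReductionReport]:
    """Aggregate a molecule stream into frequency-counted substructure records.

    ``mode="scaffold"``: each parseable molecule contributes exactly one key —
    its scaffold, or its major chain when acyclic.  ``mode="substituent"``:
    each molecule contributes one key per extracted substituent.  Activity
    flags and target-class labels in the input annotations are aggregated into
    ``activity_ratio`` and ``class_fractions``.  Unparseable SMILES are
    skipped and tallied in the report.

    Reduction is cached per distinct SMILES string, so collections with many
    duplicate structures aggregate quickly.
    """
    if mode not in ("scaffold", "substituent"):
        raise ValueError(f"unknown mode {mode!r}")

    counts: Counter[tuple[str, Kind]] = Counter()
    n_active: Counter[tuple[str, Kind]] = Counter()
    n_flagged: Counter[tuple[str, Kind]] = Counter()
    class_tally: dict[tuple[str, Kind], Counter] = {}
    report = ReductionReport()
    cache: dict[str, list[tuple[str, Kind]] | None] = {}

    for mi in mols:
        keys = cache.get(mi.smiles, ...)
        if keys is ...:
            keys = _reduce_one(mi.smiles, mode, keep_exocyclic, max_substituent_atoms)
            cache[mi.smiles] = keys
        if keys is None:
            report.failed += 1
            continue
        report.parsed += 1
        ann = mi.annotations or {}
        for key in keys:
            counts[key] += 1
            if "is_active" in ann:
                n_flagged[key] += 1
                if ann["is_active"]:
                    n_active[key] += 1
            tc = ann.get("target_class")
            if tc:
                class_tally.setdefault(key, Counter())[str(tc)] += 1

    records = []
    for (smi, kind), freq in counts.items():
        ratio = (n_active[(smi, kind)] / n_flagged[(smi, kind)]
                 if n_flagged[(smi, kind)] else None)
        fractions = {c: n / freq
                     for c, n in sorted(class_tally.get((smi, kind), {}).items())}
        records.append(SubstructureRecord(smi, kind, freq, ratio, fractions))
    records.sort(key=lambda r: (-r.frequency, r.canonical_smiles))
    return records, report


def _reduce_one(smiles: str, mode: str, keep_exocyclic: bool,
                max_substituent_atoms: int) -> list[tuple[str, Kind]] | None:
    mol = parse_smiles(smiles)
    if mol is None:
        return None
    if mode == "substituent":
        return [(smi, Kind.SUBSTITUENT)
                for smi in extract_substituents(mol, max_substituent_atoms,
                                                keep_exocyclic)]
    core = extract_scaffold(mol, keep_exocyclic=keep_exocyclic)
    if core is not None:
        return [(Chem.MolToSmiles(core), Kind.SCAFFOLD)]
    try:
        chain = extract_major_chain(mol)
    except ValueError:
        return None
    return [(Chem.MolToSmiles(chain), Kind.CHAIN)]
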