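"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (path
enumeration, exhaustive grid search) so they stay independent of the code
paths they check.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from moleculecloud.layout import CloudItem, LayoutConfig
from moleculecloud.substructure import _path_submol

# --- random acyclic molecules for the major-chain oracle --------------------

_ELEMENTS = [(6, 4), (6, 4), (6, 4), (6, 4), (7, 3), (8, 2), (16, 2), (9, 1), (17, 1)]


def random_acyclic_mol(rng: np.random.Generator, max_atoms: int = 12) -> Chem.Mol:
    """Random tree-shaped molecule with 2..max_atoms heavy atoms."""
    while True:
        n = int(rng.integers(2, max_atoms + 1))
        em = Chem.RWMol()
        z0, _ = _ELEMENTS[int(rng.integers(len(_ELEMENTS)))]
        em.AddAtom(Chem.Atom(z0))
        valence = {0: dict(_ELEMENTS)[z0]}
        for _ in range(n - 1):
            anchors = [i for i, v in valence.items() if v > 0]
            if not anchors:
                break
            anchor = int(anchors[int(rng.integers(len(anchors)))])
            z, vmax = _ELEMENTS[int(rng.integers(len(_ELEMENTS)))]
            idx = em.AddAtom(Chem.Atom(z))
            em.AddBond(anchor, idx, Chem.BondType.SINGLE)
            valence[anchor] -= 1
            valence[idx] = vmax - 1
        mol = em.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        if mol.GetNumAtoms() >= 2:
            return mol


def brute_force_major_chain(mol: Chem.Mol) -> str:
    """All simple paths, ranked by (length, heteroatom count, smallest
    canonical SMILES); returns the winning path's canonical SMILES."""
    g = nx.Graph()
    g.add_nodes_from(a.GetIdx() for a in mol.GetAtoms())
    g.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds())
    hetero = {a.GetIdx(): a.GetAtomicNum() not in (1, 6) for a in mol.GetAtoms()}
    best = None
    nodes = sorted(g.nodes)
    for i in nodes:
        for j in nodes:
            if i >= j:
                continue
            for path in nx.all_simple_paths(g, i, j):
                smi = Chem.MolToSmiles(_path_submol(mol, path))
                key = (-len(path), -sum(hetero[k] for k in path), smi)
                if best is None or key < best:
                    best = key
    assert best is not None
    return best[2]


# --- exhaustive greedy-placement oracle -------------------------------------

def exhaustive_greedy_place(items: list[CloudItem], cfg: LayoutConfig) -> list[CloudItem]:
    """Independent re-implementation of the greedy pass as plain scalar
    loops: full enumeration of every grid point at every step, strict-<
    minimum so the first candidate in row-major order wins ties."""
    order = sorted(items, key=lambda it: (-it.area, it.id))
    xs = np.linspace(0.0, cfg.canvas_width, cfg.grid_nx)
    ys = np.linspace(0.0, cfg.canvas_height, cfg.grid_ny)
    w_d = cfg.distance_weight
    placed: list[CloudItem] = []
    for it in order:
        it = CloudItem(it.id, it.width, it.height)
        if not placed:
            it.x, it.y = cfg.canvas_width / 2.0, cfg.canvas_height / 2.0
        else:
            best_score, best_xy = None, None
            for y in ys:           # row-major: y outer, x inner
                for x in xs:
                    if (x - it.width / 2 < 0 or x + it.width / 2 > cfg.canvas_width
                            or y - it.height / 2 < 0 or y + it.height / 2 > cfg.canvas_height):
                        continue
                    # accumulate the two sums separately, then weight — the
                    # same arithmetic form as the engine, so exact ties
                    # resolve identically
                    ov_sum = dist_sum = 0.0
                    for q in placed:
                        ox = (min(x + it.width / 2, q.x + q.width / 2)
                              - max(x - it.width / 2, q.x - q.width / 2))
                        oy = (min(y + it.height / 2, q.y + q.height / 2)
                              - max(y - it.height / 2, q.y - q.height / 2))
                        ov_sum += max(ox, 0.0) * max(oy, 0.0)
                        dist_sum += float(np.hypot(x - q.x, y - q.y))
                    s = cfg.w_overlap * ov_sum + w_d * dist_sum
                    if best_score is None or s < best_score:
                        best_score, best_xy = s, (float(x), float(y))
            if best_xy is None:
                best_xy = (cfg.canvas_width / 2.0, cfg.canvas_height / 2.0)
            it.x, it.y = best_xy
        placed.append(it)
    return placed


def random_items(rng: np.random.Generator, n: int, lo: float = 5.0,
                 hi: float = 60.0) -> list[CloudItem]:
    return [CloudItem(f"r{k}", float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
            for k in range(n)]


def powerlaw_items(rng: np.random.Generator, n: int = 150,
                   base: float = 120.0, exponent: float = 0.5) -> list[CloudItem]:
    """Rectangle sizes shaped like log-scaled power-law frequencies."""
    out = []
    for k in range(n):
        s = base * (k + 1) ** (-exponent)
        out.append(CloudItem(f"p{k}", s * float(rng.uniform(0.9, 1.5)),
                             0.7 * s * float(rng.uniform(0.9, 1.5))))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120706)
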