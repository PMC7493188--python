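"""Intermolecular contact maps, Hamming distances and steric clashes.

Two residues on different chains are in contact when any pair of their
heavy atoms is closer than a cutoff distance (5 Å by default).  The set of
such residue pairs — the contact map — is the fingerprint on which both
consensus scoring and contact-based clustering operate.  The number of
contacts by which two maps differ (the symmetric-difference size) is the
Hamming distance between the corresponding models.

All distance comparisons are strict ``<``: neighbor candidates found by the
k-d tree at ``<= cutoff`` are re-filtered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import Model

__all__ = [
    "Contact",
    "ContactMap",
    "make_contact",
    "compute_contact_map",
    "hamming_distance",
    "count_clashes",
    "contact_table",
]

# a contact is a canonically ordered pair of (chain, residue) endpoints
Contact = tuple[tuple[str, int], tuple[str, int]]


def make_contact(
    a: tuple[str, int], b: tuple[str, int], symmetric: bool = False
) -> Contact:
    """Canonical contact key for endpoints on two different chains.

    With ``symmetric=True`` (identical-sequence chain pair, e.g. a
    homodimer) the key is made invariant to swapping the two chain labels:
    the smaller residue index is put on the first chain.  A pose and its
    chain-relabeled mirror then produce identical maps, protecting the
    consensus from arbitrary A/B labeling in the ensemble.
    """
    if a[0] == b[0]:
        raise ValueError("contacts are intermolecular: chains must differ")
    if symmetric:
        c1, c2 = sorted((a[0], b[0]))
        i, j = sorted((a[1], b[1]))
        return ((c1, i), (c2, j))
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ContactMap:
    """Set of intermolecular residue contacts of one model."""

    model_id: str
    contacts: frozenset[Contact]

    @property
    def M(self) -> int:
        """Total number of contacts (the normalization of the raw score)."""
        return len(self.contacts)


def _group_atoms(
    model: Model, chains: Iterable[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinates, residue numbers and row indices of contact-eligible atoms."""
    arr = model.arrays()
    mask = model.chain_mask(chains)
    if model.contact_residues is not None:
        elig = np.zeros(len(model.atoms), dtype=bool)
        for chain, residues in model.contact_residues.items():
            if residues:
                elig |= (arr["chain"] == chain) & np.isin(
                    arr["res_seq"], sorted(residues)
                )
        mask = mask & elig
    idx = np.flatnonzero(mask)
    return arr["coords"][idx], arr["res_seq"][idx], idx


def _chain_pairs(
    model: Model, chain_pair: tuple[Sequence[str], Sequence[str]] | None
) -> list[tuple[str, str]]:
    chains = model.chains
    if chain_pair is None:
        return [(c1, c2) for i, c1 in enumerate(chains) for c2 in chains[i + 1 :]]
    g1, g2 = chain_pair
    missing = (set(g1) | set(g2)) - set(chains)
    if missing:
        raise ValueError(f"chains {sorted(missing)} not present in {model.model_id}")
    return [(c1, c2) for c1 in g1 for c2 in g2 if c1 != c2]


def compute_contact_map(
    model: Model,
    cutoff: float = 5.0,
    chain_pair: tuple[Sequence[str], Sequence[str]] | None = None,
    symmetric: bool = False,
) -> ContactMap:
    """Contact map of a model at the given heavy-atom distance cutoff.

    ``chain_pair`` restricts the analysis to contacts between two chain
    groups (default: all inter-chain pairs).  ``symmetric=True`` applies
    the homodimer key canonicalization of :func:`make_contact`.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(model.chains) < 2:
        raise ValueError(f"{model.model_id}: need at least 2 chains")
    contacts: set[Contact] = set()
    for c1, c2 in _chain_pairs(model, chain_pair):
        xyz1, res1, _ = _group_atoms(model, [c1])
        xyz2, res2, _ = _group_atoms(model, [c2])
        if len(xyz1) == 0 or len(xyz2) == 0:
            continue
        t1, t2 = cKDTree(xyz1), cKDTree(xyz2)
        for i, js in enumerate(t1.query_ball_tree(t2, r=cutoff)):
            if not js:
                continue
            js = np.asarray(js)
            d = np.linalg.norm(xyz2[js] - xyz1[i], axis=1)
            for j in js[d < cutoff]:
                contacts.add(
                    make_contact((c1, int(res1[i])), (c2, int(res2[j])), symmetric)
                )
    return ContactMap(model.model_id, frozenset(contacts))


def hamming_distance(x: ContactMap, y: ContactMap) -> int:
    """Absolute number of differing contacts between two models."""
    return len(x.contacts ^ y.contacts)


def count_clashes(
    model: Model,
    cutoff: float = 3.0,
    chain_pair: tuple[Sequence[str], Sequence[str]] | None = None,
) -> int:
    """Number of inter-chain heavy-atom pairs closer than ``cutoff``.

    Counts atom pairs, not residue pairs.  All residues participate —
    steric overlap is a property of the coordinates, not of the alignment.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    arr = model.arrays()
    n = 0
    for c1, c2 in _chain_pairs(model, chain_pair):
        xyz1 = arr["coords"][arr["chain"] == c1]
        xyz2 = arr["coords"][arr["chain"] == c2]
        if len(xyz1) == 0 or len(xyz2) == 0:
            continue
        t1, t2 = cKDTree(xyz1), cKDTree(xyz2)
        for i, js in enumerate(t1.query_ball_tree(t2, r=cutoff)):
            if js:
                d = np.linalg.norm(xyz2[np.asarray(js)] - xyz1[i], axis=1)
                n += int((d < cutoff).sum())
    return n


def contact_table(
    model: Model,
    cutoff: float = 5.0,
    chain_pair: tuple[Sequence[str], Sequence[str]] | None = None,
    symmetric: bool = False,
) -> pd.DataFrame:
    """Per-contact table with residue names and minimum atom distance.

    Columns: chain1, res1, resname1, chain2, res2, resname2, min_distance.
    """
    arr = model.arrays()
    resname: dict[tuple[str, int], str] = {}
    for a in model.atoms:
        resname.setdefault((a.chain_id, a.res_seq), a.res_name)
    mind: dict[Contact, float] = {}
    for c1, c2 in _chain_pairs(model, chain_pair):
        xyz1, res1, _ = _group_atoms(model, [c1])
        xyz2, res2, _ = _group_atoms(model, [c2])
        if len(xyz1) == 0 or len(xyz2) == 0:
            continue
        t1, t2 = cKDTree(xyz1), cKDTree(xyz2)
        for i, js in enumerate(t1.query_ball_tree(t2, r=cutoff)):
            if not js:
                continue
            js = np.asarray(js)
            d = np.linalg.norm(xyz2[js] - xyz1[i], axis=1)
            for j, dij in zip(js[d < cutoff], d[d < cutoff]):
                key = make_contact((c1, int(res1[i])), (c2, int(res2[j])), symmetric)
                if dij < mind.get(key, np.inf):
                    mind[key] = float(dij)
    rows = []
    for ((ch1, r1), (ch2, r2)), d in sorted(mind.items()):
        rows.append(
            {
                "chain1": ch1,
                "res1": r1,
                "resname1": resname.get((ch1, r1), "UNK"),
                "chain2": ch2,
                "res2": r2,
                "resname2": resname.get((ch2, r2), "UNK"),
                "min_distance": round(d, 3),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chain1", "res1", "resname1",
            "chain2", "res2", "resname2", "min_distance",
        ],
    )
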