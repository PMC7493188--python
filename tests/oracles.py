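"""Independent brute-force reference implementations used only by tests.

Every routine here recomputes a quantity along a different path than the
package: all-pairs loops instead of spatial trees, explicit tallies
instead of incremental ones, direct max-over-members agglomeration instead
of Lance-Williams updates, SVD Kabsch instead of quaternion alignment.
"""

from __future__ import annotations

import numpy as np

from consrank.contacts import ContactMap, make_contact
from consrank.model_io import Model


def brute_force_contact_set(model: Model, cutoff: float, symmetric: bool = False):
    """All inter-chain residue pairs with any heavy-atom distance < cutoff."""
    contacts = set()
    atoms = model.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            if a.chain_id == b.chain_id:
                continue
            d = np.linalg.norm(np.asarray(a.coord) - np.asarray(b.coord))
            if d < cutoff:
                contacts.add(
                    make_contact(
                        (a.chain_id, a.res_seq), (b.chain_id, b.res_seq), symmetric
                    )
                )
    return contacts


def brute_force_clashes(model: Model, cutoff: float) -> int:
    n = 0
    atoms = model.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            if a.chain_id == b.chain_id:
                continue
            if np.linalg.norm(np.asarray(a.coord) - np.asarray(b.coord)) < cutoff:
                n += 1
    return n


def brute_force_scores(maps: list[ContactMap]) -> dict[str, tuple[float, float]]:
    """Conservation tallies and per-model scores by explicit loops."""
    n = len(maps)
    counts: dict = {}
    for m in maps:
        for c in m.contacts:
            counts[c] = counts.get(c, 0) + 1
    out = {}
    for m in maps:
        S = 0.0
        for c in m.contacts:
            S += counts[c] / n
        out[m.model_id] = (S, S / len(m.contacts))
    return out


def naive_complete_linkage(condensed: np.ndarray, n: int) -> np.ndarray:
    """O(n^3) agglomeration recomputing every inter-cluster distance as the
    max over member pairs; ties resolved by smallest original member index."""
    D = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = condensed[k]
            k += 1
    clusters = {i: ([i], i) for i in range(n)}  # id -> (members, creation id)
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        ids = sorted(clusters)
        best = None
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                u, v = ids[x], ids[y]
                mu, mv = clusters[u][0], clusters[v][0]
                d = D[np.ix_(mu, mv)].max()
                key = (d,) + tuple(sorted((min(mu), min(mv))))
                if best is None or key < best[0]:
                    best = (key, u, v)
        _, u, v = best
        mu, mv = clusters[u][0], clusters[v][0]
        Z[step] = (min(u, v), max(u, v), best[0][0], len(mu) + len(mv))
        del clusters[u], clusters[v]
        clusters[next_id] = (mu + mv, next_id)
        next_id += 1
    return Z


def kabsch_svd(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal superposition via SVD; returns fitted mobile and its RMSD."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    P, Q = mobile - mc, target - tc
    H = P.T @ Q
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    fitted = P @ R.T + tc
    return fitted, float(np.sqrt(((fitted - target) ** 2).sum(axis=1).mean()))


def dense_sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
               n_points: int = 10000) -> float:
    """High-resolution quadrature surface with an independent point set
    (random uniform sphere sampling, fixed seed)."""
    rng = np.random.default_rng(12345)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    total = 0.0
    inflated = radii + probe
    for i in range(len(coords)):
        surf = coords[i] + inflated[i] * pts
        free = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.linalg.norm(surf - coords[j], axis=1) >= inflated[j]
        total += free.mean() * 4.0 * np.pi * inflated[i] ** 2
    return total
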