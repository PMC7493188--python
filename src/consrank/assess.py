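"""CAPRI-style quality assessment of docking models against a reference.

Three measures, computed after the model and the reference (native)
structure have been consistently numbered:

* ``fnat`` — the fraction of native intermolecular residue contacts
  (atom pairs within 5 Å) reproduced by the model;
* ``L-rms`` — backbone RMSD of the ligand (smaller partner) after optimal
  superposition of the receptor (larger partner);
* ``I-rms`` — backbone RMSD over the native interface residues (those
  with a heavy atom within 10 Å of the partner) after their own optimal
  superposition.

Models are then binned into the standard quality classes, evaluated
best-first:

    high        fnat >= 0.5 and (L-rms <= 1.0  or I-rms <= 1.0)
    medium      fnat >= 0.3 and (L-rms <= 5.0  or I-rms <= 2.0)
    acceptable  fnat >= 0.1 and (L-rms <= 10.0 or I-rms <= 4.0)
    incorrect   otherwise

The medium/acceptable tiers follow the criteria of Lensink et al. (2016)
Proteins 84 Suppl 1, 323-348; the threshold table is module data and can
be overridden.  For two-chain complexes with identical sequences the chain
correspondence is ambiguous, so both assignments are evaluated and the
better one kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .contacts import ContactMap, compute_contact_map
from .model_io import Model

__all__ = [
    "BACKBONE_ATOMS",
    "CAPRI_THRESHOLDS",
    "AssessmentResult",
    "fnat",
    "ligand_rms",
    "interface_rms",
    "classify",
    "assess_model",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# (class, min fnat, max L-rms, max I-rms); a class applies when
# fnat >= min and (L-rms <= max_L or I-rms <= max_I), best class first
CAPRI_THRESHOLDS: tuple[tuple[str, float, float, float], ...] = (
    ("high", 0.5, 1.0, 1.0),
    ("medium", 0.3, 5.0, 2.0),
    ("acceptable", 0.1, 10.0, 4.0),
)


@dataclass(frozen=True)
class AssessmentResult:
    model_id: str
    fnat: float
    L_rms: float
    I_rms: float
    quality: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.fnat <= 1.0:
            raise ValueError("fnat must be in [0, 1]")
        if self.L_rms < 0 or self.I_rms < 0:
            raise ValueError("RMSD values must be non-negative")


def fnat(model_map: ContactMap, native_map: ContactMap) -> float:
    """Fraction of native contacts reproduced by the model."""
    if native_map.M == 0:
        raise ValueError("native contact map is empty")
    return len(model_map.contacts & native_map.contacts) / native_map.M


def _backbone_coords(
    model: Model, chains: Sequence[str], residues: set[tuple[str, int]] | None = None
) -> dict[tuple[str, int, str], np.ndarray]:
    out = {}
    wanted = set(chains)
    for a in model.atoms:
        if a.chain_id not in wanted or a.atom_name not in BACKBONE_ATOMS:
            continue
        if residues is not None and (a.chain_id, a.res_seq) not in residues:
            continue
        out[(a.chain_id, a.res_seq, a.atom_name)] = np.asarray(a.coord)
    return out


def _matched(
    model: Model, native: Model, chains: Sequence[str],
    residues: set[tuple[str, int]] | None = None,
    chain_map: dict[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired backbone coordinate arrays (model, native) for shared atoms.

    ``chain_map`` translates model chain labels to native labels (used to
    evaluate the swapped assignment of a homodimer).
    """
    chain_map = chain_map or {c: c for c in chains}
    model_bb = _backbone_coords(model, list(chain_map), None)
    native_bb = _backbone_coords(native, chains, residues)
    xs, ys = [], []
    for (ch, res, name), x in sorted(model_bb.items()):
        key = (chain_map[ch], res, name)
        if residues is not None and (chain_map[ch], res) not in residues:
            continue
        y = native_bb.get(key)
        if y is not None:
            xs.append(x)
            ys.append(y)
    if not xs:
        raise ValueError("no matched backbone atoms between model and native")
    return np.asarray(xs), np.asarray(ys)


def _kabsch_transform(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rotation + centroids superposing mobile onto target."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.as_matrix(), mc, tc


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def _partition_by_size(native: Model) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(receptor chains, ligand chains): receptor is the larger group."""
    chains = native.chains
    if len(chains) != 2:
        # multi-chain: first chain group vs rest, larger group = receptor
        g1, g2 = (chains[0],), tuple(chains[1:])
    else:
        g1, g2 = (chains[0],), (chains[1],)
    n1 = sum(native.n_residues(c) for c in g1)
    n2 = sum(native.n_residues(c) for c in g2)
    return (g1, g2) if n1 >= n2 else (g2, g1)


def ligand_rms(
    model: Model, native: Model, chain_map: dict[str, str] | None = None
) -> float:
    """Backbone RMSD of the ligand after optimal receptor superposition."""
    receptor, ligand = _partition_by_size(native)
    rx, ry = _matched(model, native, receptor, chain_map=chain_map)
    R, mc, tc = _kabsch_transform(rx, ry)
    lx, ly = _matched(model, native, ligand, chain_map=chain_map)
    lx_fit = (lx - mc) @ R.T + tc
    return _rmsd(lx_fit, ly)


def native_interface_residues(native: Model, cutoff: float = 10.0) -> set[tuple[str, int]]:
    """Native residues with any heavy atom within ``cutoff`` of the partner."""
    receptor, ligand = _partition_by_size(native)
    arr = native.arrays()
    out: set[tuple[str, int]] = set()
    for g_self, g_other in ((receptor, ligand), (ligand, receptor)):
        mask_s = native.chain_mask(g_self)
        mask_o = native.chain_mask(g_other)
        tree = cKDTree(arr["coords"][mask_o])
        d, _ = tree.query(arr["coords"][mask_s], k=1)
        for chain, res, di in zip(
            arr["chain"][mask_s], arr["res_seq"][mask_s], d
        ):
            if di < cutoff:
                out.add((str(chain), int(res)))
    return out


def interface_rms(
    model: Model, native: Model, chain_map: dict[str, str] | None = None
) -> float:
    """Backbone RMSD over native interface residues after their superposition."""
    residues = native_interface_residues(native)
    if not residues:
        raise ValueError("native interface is empty")
    xs, ys = _matched(model, native, native.chains, residues=residues, chain_map=chain_map)
    R, mc, tc = _kabsch_transform(xs, ys)
    return _rmsd((xs - mc) @ R.T + tc, ys)


def classify(
    fnat_value: float,
    L_rms: float,
    I_rms: float,
    thresholds: Sequence[tuple[str, float, float, float]] = CAPRI_THRESHOLDS,
) -> str:
    """Quality class from the three assessment measures, best tier first."""
    for name, fmin, lmax, imax in thresholds:
        if fnat_value >= fmin and (L_rms <= lmax or I_rms <= imax):
            return name
    return "incorrect"


def assess_model(
    model: Model,
    native: Model,
    contact_cutoff: float = 5.0,
    symmetric: bool | None = None,
) -> AssessmentResult:
    """Full CAPRI-style assessment of one model against the native.

    For a two-chain complex whose chains share length (homodimer-like)
    both chain assignments are tried and the one with the smaller ligand
    RMSD is reported.
    """
    chains = native.chains
    if symmetric is None:
        symmetric = (
            len(chains) == 2
            and native.n_residues(chains[0]) == native.n_residues(chains[1])
        )
    native_map = compute_contact_map(native, cutoff=contact_cutoff, symmetric=symmetric)
    model_map = compute_contact_map(model, cutoff=contact_cutoff, symmetric=symmetric)
    f = fnat(model_map, native_map)

    chain_maps: list[dict[str, str] | None] = [None]
    if symmetric and len(model.chains) == 2:
        a, b = model.chains
        chain_maps.append({a: b, b: a})
    best: tuple[float, float] | None = None
    for cm in chain_maps:
        try:
            L = ligand_rms(model, native, chain_map=cm)
            I = interface_rms(model, native, chain_map=cm)
        except ValueError:
            continue
        if best is None or L < best[0]:
            best = (L, I)
    if best is None:
        raise ValueError(f"{model.model_id}: no atom correspondence with native")
    L, I = best
    return AssessmentResult(
        model_id=model.model_id,
        fnat=f,
        L_rms=L,
        I_rms=I,
        quality=classify(f, L, I),
    )
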