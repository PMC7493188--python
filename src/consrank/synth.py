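"""Synthetic docking-decoy ensembles with known ground truth.

Real scoring sets from blind docking experiments mix a fraction of
near-native poses (many predictors converging on the right interface,
especially when good templates exist) with incorrect poses scattered over
the partner's surface.  This module emulates that structure on an
idealized homodimer so that every pipeline stage — filtering, consensus
scoring, clustering, interface analysis, selection, quality assessment —
can be exercised end to end with a known answer:

* a deterministic reference dimer of two idealized poly-alanine helices
  (backbone N, CA, C, O plus CB) docked side by side;
* *near-native* decoys: the reference with a small rigid-body jitter of
  chain B (sub-Å translation, few-degree rotation);
* *random* decoys: chain B at a uniformly random orientation, slid along a
  random direction until it touches chain A (at least one contact at 5 Å,
  no steric overlap), so every decoy survives the zero-contact filter;
* optional *swapped-monomer* decoys: jittered poses of an alternative
  reference in which chain A adopts a different (bent) conformation,
  emulating ensembles whose monomers disagree conformationally;
* optional *clash-injected* decoys: near-native poses pushed into overlap
  until they exceed the clash-exclusion threshold, for testing the
  exclusion rule.

File names are shuffled, as in anonymized scoring sets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .contacts import Contact, ContactMap, compute_contact_map, count_clashes
from .model_io import AtomRecord, Model, TargetSpec, write_model

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_reference_dimer",
    "make_swapped_reference",
    "generate_ensemble",
    "target_spec",
]

# local-frame atom offsets (Å) relative to CA: along tangent t, outward
# radial u; CB points outward, O roughly along the helix normal w
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic scoring set."""

    n_models: int = 100
    planted_fraction: float = 0.3
    jitter_translation: float = 0.5   # Å std-dev, near-native chain-B shift
    jitter_rotation: float = 2.0      # degrees std-dev, near-native chain-B spin
    n_residues_per_chain: int = 30
    monomer_swap_fraction: float = 0.0
    inject_clashes: int = 0           # number of clash-injected decoys
    contact_cutoff: float = 5.0
    clash_max: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("need at least 2 models")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0.0 <= self.monomer_swap_fraction <= 1.0:
            raise ValueError("monomer_swap_fraction must be in [0, 1]")
        if self.n_residues_per_chain < 5:
            raise ValueError("chains need at least 5 residues")


@dataclass
class GroundTruth:
    """What the generator knows about the ensemble it produced."""

    reference: Model
    labels: dict[str, str] = field(default_factory=dict)
    true_contacts: frozenset[Contact] = frozenset()

    def ids_with_label(self, label: str) -> list[str]:
        return [mid for mid, lab in self.labels.items() if lab == label]


def _helix_coords(n_res: int, phase: float = 0.0) -> dict[str, np.ndarray]:
    """Idealized alpha-helical backbone + CB, helix axis along z."""
    i = np.arange(n_res, dtype=float)
    theta = i * _HELIX_TWIST + phase
    z = (i - (n_res - 1) / 2.0) * _HELIX_RISE
    ca = np.column_stack(
        (_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), z)
    )
    # local frame: tangent along the chain, radial outward, and their normal
    t = np.gradient(ca, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    u = ca.copy()
    u[:, 2] = 0.0
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    w = np.cross(t, u)
    return {
        "N": ca - 1.2 * t - 0.5 * u,
        "CA": ca,
        "C": ca + 1.2 * t - 0.5 * u,
        "O": ca + 1.2 * t - 0.3 * u + 1.1 * w,
        "CB": ca + 1.53 * u,
    }


_HAIRPIN_SEP = 9.5           # Å between the two arm axes (helix-pair packing)
_HAIRPIN_PHASE = np.deg2rad(40.0)   # arm-2 spin maximizing inter-arm clearance


def _hairpin_coords(n_res: int) -> dict[str, np.ndarray]:
    """Helical-hairpin monomer: two packed antiparallel helices.

    A globular two-helix bundle rather than a bare cylinder, so random
    docked poses present genuinely different surface patches instead of
    collapsing into the one-parameter family of side-by-side cylinder
    packings.  Arm 1 carries residues 1..n/2, arm 2 the rest (the turn is
    idealized away).
    """
    half = n_res // 2
    arm1 = _helix_coords(half)
    arm2 = _helix_coords(n_res - half, phase=_HAIRPIN_PHASE)
    Rx = Rotation.from_euler("x", 180, degrees=True).as_matrix()
    shift = np.array([_HAIRPIN_SEP, 0.0, 0.0])
    return {
        k: np.vstack((arm1[k], arm2[k] @ Rx.T + shift)) for k in arm1
    }


def _chain_atoms(coords: dict[str, np.ndarray], chain_id: str) -> list[AtomRecord]:
    atoms = []
    n_res = len(coords["CA"])
    for r in range(n_res):
        for name in ("N", "CA", "C", "O", "CB"):
            xyz = coords[name][r]
            atoms.append(
                AtomRecord(
                    chain_id=chain_id,
                    res_seq=r + 1,
                    icode="",
                    res_name="ALA",
                    atom_name=name,
                    element=name[0],
                    coord=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                )
            )
    return atoms


def _transform_chain(model: Model, chain: str, R: np.ndarray, t: np.ndarray) -> Model:
    """Rigid transform of one chain about its centroid."""
    arr = model.arrays()
    mask = model.chain_mask([chain])
    centroid = arr["coords"][mask].mean(axis=0)
    atoms = []
    for a, m in zip(model.atoms, mask):
        if m:
            x = np.asarray(a.coord) - centroid
            x = R @ x + centroid + t
            a = AtomRecord(
                a.chain_id, a.res_seq, a.icode, a.res_name, a.atom_name, a.element,
                (float(x[0]), float(x[1]), float(x[2])),
            )
        atoms.append(a)
    return Model(model.model_id, atoms)


def _min_interchain_distance(model: Model) -> float:
    arr = model.arrays()
    a = arr["coords"][arr["chain"] == "A"]
    b = arr["coords"][arr["chain"] == "B"]
    from scipy.spatial import cKDTree

    d, _ = cKDTree(a).query(b, k=1)
    return float(d.min())


def _dock_side_by_side(chain_a: list[AtomRecord], chain_b_coords: dict[str, np.ndarray],
                       gap: float = 3.2,
                       direction: tuple[float, float, float] = (0.0, 1.0, 0.0)) -> Model:
    """Slide chain B along ``direction`` until the surface gap is reached."""
    u = np.asarray(direction, dtype=float)
    u /= np.linalg.norm(u)
    offset = 40.0
    for _ in range(8):
        shifted = {k: v + offset * u for k, v in chain_b_coords.items()}
        model = Model("reference", chain_a + _chain_atoms(shifted, "B"))
        m = _min_interchain_distance(model)
        if abs(m - gap) < 1e-9:
            break
        offset -= m - gap
    return model


def make_reference_dimer(spec: SyntheticSpec) -> Model:
    """Deterministic idealized homodimer with a contiguous interface.

    The second hairpin approaches along the normal of the first one's
    helix-pair plane, so both arms of both monomers engage: a four-helix
    interface of well over 10 residue-pair contacts at the 5 Å cutoff
    (24 for the default 30-residue chains) and no steric clashes.
    """
    coords = _hairpin_coords(spec.n_residues_per_chain)
    chain_a = _chain_atoms(coords, "A")
    return _dock_side_by_side(chain_a, coords)


def make_swapped_reference(spec: SyntheticSpec) -> Model:
    """Reference with an alternative chain-A conformation (bent helix).

    Chain A is a single straight helix instead of the folded hairpin — a
    different monomer fold presenting a different interface, as happens in
    ensembles where predictors disagree on the monomer structure itself.
    """
    coords_a = _helix_coords(spec.n_residues_per_chain)
    chain_a = _chain_atoms(coords_a, "A")
    coords_b = _hairpin_coords(spec.n_residues_per_chain)
    return _dock_side_by_side(chain_a, coords_b)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def _jittered(reference: Model, rng: np.random.Generator, spec: SyntheticSpec) -> Model:
    angle = rng.normal(0.0, spec.jitter_rotation)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
    t = rng.normal(0.0, spec.jitter_translation, size=3)
    return _transform_chain(reference, "B", R, t)


def _with_chain_coords(model: Model, chain: str, xyz: np.ndarray) -> Model:
    """Copy of a model with one chain's coordinates replaced (atom order kept)."""
    atoms = []
    k = 0
    for a in model.atoms:
        if a.chain_id == chain:
            x = xyz[k]
            k += 1
            a = AtomRecord(
                a.chain_id, a.res_seq, a.icode, a.res_name, a.atom_name, a.element,
                (float(x[0]), float(x[1]), float(x[2])),
            )
        atoms.append(a)
    return Model(model.model_id, atoms)


def _random_decoy(reference: Model, rng: np.random.Generator, spec: SyntheticSpec,
                  max_tries: int = 60) -> Model:
    """Chain B at a random orientation, slid until it touches chain A."""
    from scipy.spatial import cKDTree

    arr = reference.arrays()
    mask_b = reference.chain_mask(["B"])
    xyz_a = arr["coords"][~mask_b]
    xyz_b0 = arr["coords"][mask_b]
    centroid_a = xyz_a.mean(axis=0)
    centroid_b = xyz_b0.mean(axis=0)
    tree_a = cKDTree(xyz_a)

    def n_pairs_within(xyz_b: np.ndarray, r: float) -> int:
        return sum(len(hits) for hits in tree_a.query_ball_point(xyz_b, r=r))

    clash_budget = min(10, spec.clash_max)
    for _ in range(max_tries):
        R = _random_rotation(rng)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        gap = rng.uniform(3.4, 4.6)
        # start far out along u, then walk in until the surface gap is hit
        xyz_b = (xyz_b0 - centroid_b) @ R.T + centroid_a + 60.0 * u
        ok = False
        for _ in range(8):
            m = float(tree_a.query(xyz_b, k=1)[0].min())
            if abs(m - gap) < 0.05:
                ok = True
                break
            xyz_b = xyz_b - min(m - gap, 30.0) * u
        if not ok:
            continue
        # press the chains into a snug fit: incorrect poses in real scoring
        # sets bury a substantial patch, often with a few mild clashes but
        # nowhere near the exclusion level
        for _ in range(12):
            closer = xyz_b - 0.3 * u
            if n_pairs_within(closer, 3.0) > clash_budget:
                break
            xyz_b = closer
        if n_pairs_within(xyz_b, spec.contact_cutoff) < 1:
            continue
        model = _with_chain_coords(reference, "B", xyz_b)
        cmap = compute_contact_map(model, cutoff=spec.contact_cutoff, symmetric=True)
        if cmap.M >= 1 and count_clashes(model, 3.0) <= clash_budget:
            return model
    raise RuntimeError("rejection sampling failed to place a random decoy")


def _clash_decoy(reference: Model, rng: np.random.Generator, spec: SyntheticSpec) -> Model:
    """Near-native pose pushed into steric overlap past the clash threshold."""
    model = _jittered(reference, rng, spec)
    arr = model.arrays()
    mask_b = model.chain_mask(["B"])
    direction = arr["coords"][~mask_b].mean(axis=0) - arr["coords"][mask_b].mean(axis=0)
    direction /= np.linalg.norm(direction)
    for _ in range(40):
        model = _transform_chain(model, "B", np.eye(3), 0.4 * direction)
        if count_clashes(model, 3.0) > spec.clash_max:
            return model
    raise RuntimeError("failed to inject clashes")


def target_spec(spec: SyntheticSpec) -> TargetSpec:
    """Target sequences matching the generated models (poly-alanine dimer)."""
    seq = "A" * spec.n_residues_per_chain
    return TargetSpec(sequences={"A": seq, "B": seq})


def generate_ensemble(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> tuple[list[Model], GroundTruth]:
    """Generate a shuffled, labeled decoy ensemble.

    Returns the models (in shuffled name order) and the ground truth.
    When ``out_dir`` is given, also writes one PDB per model, the target
    FASTA and a ground-truth JSON.
    """
    rng = np.random.default_rng(spec.seed)
    reference = make_reference_dimer(spec)
    n_planted = round(spec.planted_fraction * spec.n_models)
    n_swapped = round(spec.monomer_swap_fraction * spec.n_models)
    n_clash = spec.inject_clashes
    n_random = spec.n_models - n_planted - n_swapped - n_clash
    if n_random < 0:
        raise ValueError("fractions and clash injections exceed n_models")

    swapped_ref = make_swapped_reference(spec) if n_swapped else None
    entries: list[tuple[str, Model]] = []
    for _ in range(n_planted):
        entries.append(("near-native", _jittered(reference, rng, spec)))
    for _ in range(n_swapped):
        entries.append(("swapped-monomer", _jittered(swapped_ref, rng, spec)))
    for _ in range(n_clash):
        entries.append(("clash-injected", _clash_decoy(reference, rng, spec)))
    for _ in range(n_random):
        entries.append(("random", _random_decoy(reference, rng, spec)))

    order = rng.permutation(len(entries))
    models: list[Model] = []
    labels: dict[str, str] = {}
    for slot, k in enumerate(order):
        label, model = entries[k]
        mid = f"decoy_{slot:04d}"
        models.append(Model(mid, model.atoms))
        labels[mid] = label

    ref_map = compute_contact_map(reference, cutoff=spec.contact_cutoff, symmetric=True)
    truth = GroundTruth(reference=reference, labels=labels, true_contacts=ref_map.contacts)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m in models:
            write_model(m, out / f"{m.model_id}.pdb")
        seq = "A" * spec.n_residues_per_chain
        (out / "target.fasta").write_text(f">A\n{seq}\n>B\n{seq}\n")
        (out / "ground_truth.json").write_text(
            json.dumps(
                {
                    "spec": asdict(spec),
                    "labels": labels,
                    "true_contacts": sorted(
                        [list(a) + list(b) for a, b in truth.true_contacts]
                    ),
                },
                indent=2,
            )
        )
    return models, truth
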