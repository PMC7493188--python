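"""Reading, validating, filtering and renumbering docking-model ensembles.

Scoring sets from blind docking experiments arrive as anonymized PDB files
produced by many predictors: chain identifiers and residue numbering are
inconsistent, some files are empty or truncated, and some models are not
models of the target at all.  Consensus scoring requires that corresponding
amino acids carry the same chain identifier and residue number in every
model, so the ensemble is filtered and renumbered against the target
sequences before any contact analysis.

Filtering rules (each discarded model is itemized in a :class:`FilterReport`):

* ``unreadable`` — the file could not be parsed;
* ``empty`` — no protein ATOM records;
* ``single_chain`` — only one chain identifier (no intermolecular interface);
* ``sequence_mismatch`` — some chain aligns to no target chain with
  sequence identity >= 90% and target coverage >= 70% (both required),
  or no consistent one-to-one chain assignment exists;
* ``zero_contacts`` — no intermolecular residue contact at the working
  cutoff.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio import Align

__all__ = [
    "AtomRecord",
    "Model",
    "ReadFailure",
    "FilterReport",
    "TargetSpec",
    "read_model",
    "read_ensemble",
    "write_model",
    "chain_sequence",
    "align_sequences",
    "assign_chains",
    "filter_ensemble",
    "renumber_ensemble",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy-atom record of a model."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    coord: tuple[float, float, float]

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


class Model:
    """A parsed multi-chain complex model, the unit being scored.

    Parameters
    ----------
    model_id : str
        Identifier (file stem for models read from disk).
    atoms : sequence of AtomRecord
        Heavy protein atoms, in file order.
    contact_residues : mapping chain -> set of residue numbers, optional
        When set (after renumbering), only these residues are eligible for
        contact analysis; all atoms keep their coordinates regardless.
    """

    def __init__(
        self,
        model_id: str,
        atoms: Sequence[AtomRecord],
        contact_residues: Mapping[str, frozenset[int]] | None = None,
    ) -> None:
        self.model_id = model_id
        self.atoms = list(atoms)
        self.contact_residues = (
            {c: frozenset(r) for c, r in contact_residues.items()}
            if contact_residues is not None
            else None
        )
        self._arrays: dict | None = None

    @property
    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return tuple(seen)

    def n_residues(self, chain: str | None = None) -> int:
        keys = {
            a.residue_key() for a in self.atoms if chain is None or a.chain_id == chain
        }
        return len(keys)

    # -- array views -------------------------------------------------------
    def arrays(self) -> dict:
        """Columnar numpy views of the atom list (cached)."""
        if self._arrays is None:
            self._arrays = {
                "coords": np.array([a.coord for a in self.atoms], dtype=float).reshape(
                    -1, 3
                ),
                "chain": np.array([a.chain_id for a in self.atoms]),
                "res_seq": np.array([a.res_seq for a in self.atoms], dtype=int),
                "res_name": np.array([a.res_name for a in self.atoms]),
                "atom_name": np.array([a.atom_name for a in self.atoms]),
                "element": np.array([a.element for a in self.atoms]),
            }
        return self._arrays

    def chain_mask(self, chains: Iterable[str]) -> np.ndarray:
        wanted = set(chains)
        return np.array([a.chain_id in wanted for a in self.atoms], dtype=bool)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Model({self.model_id!r}, {len(self.atoms)} atoms, chains={self.chains})"


@dataclass(frozen=True)
class ReadFailure:
    """A file that could not be turned into a scorable model."""

    model_id: str
    reason: str  # "empty" | "unreadable"
    detail: str = ""


@dataclass
class FilterReport:
    """Accounting of an ensemble filtering pass."""

    n_input: int = 0
    discarded: dict[str, list[str]] = field(default_factory=dict)
    kept_ids: list[str] = field(default_factory=list)

    def add(self, reason: str, model_id: str) -> None:
        self.discarded.setdefault(reason, []).append(model_id)

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    @property
    def n_discarded(self) -> int:
        return sum(len(v) for v in self.discarded.values())

    def check(self) -> None:
        if self.n_input != self.n_kept + self.n_discarded:
            raise AssertionError("filter report counts do not reconcile")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_kept": self.n_kept,
                "discarded": self.discarded,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["model_id\tstatus"]
        for mid in self.kept_ids:
            lines.append(f"{mid}\tkept")
        for reason in sorted(self.discarded):
            for mid in self.discarded[reason]:
                lines.append(f"{mid}\tdiscarded:{reason}")
        return "\n".join(lines) + "\n"


@dataclass
class TargetSpec:
    """Reference sequences and chain roles of the target complex.

    ``sequences`` maps canonical chain labels to one-letter sequences
    (20 standard residues + X).  ``groups`` maps each chain label to one
    of two partner groups used for interface partitioning; by default the
    first chain is one partner and all remaining chains the other.
    """

    sequences: dict[str, str]
    groups: dict[str, int] | None = None

    def __post_init__(self) -> None:
        allowed = set("ACDEFGHIKLMNPQRSTVWYX")
        for label, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty target sequence for chain {label!r}")
            bad = set(seq) - allowed
            if bad:
                raise ValueError(f"invalid residues {sorted(bad)} in chain {label!r}")
        if self.groups is None:
            labels = list(self.sequences)
            self.groups = {labels[0]: 0, **{c: 1 for c in labels[1:]}}

    @property
    def chain_labels(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def partition(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        g1 = tuple(c for c, g in self.groups.items() if g == 0)
        g2 = tuple(c for c, g in self.groups.items() if g != 0)
        if not g1 or not g2:
            raise ValueError("partition must split chains into two non-empty groups")
        return g1, g2

    def is_symmetric_pair(self) -> bool:
        """True for a homodimer-like target: two chains, identical sequence."""
        seqs = list(self.sequences.values())
        return len(seqs) == 2 and seqs[0] == seqs[1]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "TargetSpec":
        from Bio import SeqIO

        sequences = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            label = rec.id.split("|")[-1][:1].upper() if "|" in rec.id else rec.id[:1].upper()
            if label in sequences:
                raise ValueError(f"duplicate chain label {label!r} in {path}")
            sequences[label] = str(rec.seq).upper()
        if not sequences:
            raise ValueError(f"no sequences in {path}")
        return cls(sequences=sequences)


# ---------------------------------------------------------------------------
# reading / writing


def read_model(path: str | Path) -> Model | ReadFailure:
    """Parse one PDB file into a :class:`Model`.

    HETATM records, waters and hydrogens are ignored; alternate locations
    are resolved to the highest-occupancy conformer (ties: first in file).
    Chains split into several segments with the same identifier are merged.
    Unreadable or atom-free files are reported, not raised.
    """
    path = Path(path)
    model_id = path.stem
    try:
        structure = gemmi.read_pdb(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on malformed input
        return ReadFailure(model_id, "unreadable", str(exc))

    # (chain, resnum, icode, atom_name) -> (occupancy, order, AtomRecord)
    best: dict[tuple, tuple[float, int, AtomRecord]] = {}
    order = 0
    if len(structure) == 0:
        return ReadFailure(model_id, "empty", "no coordinate model")
    mdl = structure[0]
    for chain in mdl:
        for res in chain:
            if res.het_flag == "H" or res.name in _WATER_NAMES:
                continue
            for atom in res:
                elem = atom.element.name.upper()
                if elem in ("H", "D"):
                    continue
                rec = AtomRecord(
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    icode=(res.seqid.icode or " ").strip() or "",
                    res_name=res.name,
                    atom_name=atom.name,
                    element=elem,
                    coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                )
                if not all(np.isfinite(rec.coord)):
                    return ReadFailure(model_id, "unreadable", "non-finite coordinate")
                key = (rec.chain_id, rec.res_seq, rec.icode, rec.atom_name)
                occ = atom.occ if atom.occ is not None else 1.0
                prev = best.get(key)
                if prev is None or occ > prev[0]:
                    best[key] = (occ, order, rec)
                order += 1
    if not best:
        return ReadFailure(model_id, "empty", "no protein ATOM records")
    records = [rec for _, _, rec in sorted(best.values(), key=lambda t: t[1])]
    return Model(model_id, records)


def read_ensemble(paths: Iterable[str | Path]) -> tuple[list[Model], list[ReadFailure]]:
    """Read many PDB files; split results into models and failures."""
    models: list[Model] = []
    failures: list[ReadFailure] = []
    for p in paths:
        out = read_model(p)
        (models if isinstance(out, Model) else failures).append(out)  # type: ignore[arg-type]
    return models, failures


def write_model(model: Model, path: str | Path) -> None:
    """Write a model back to PDB format."""
    st = gemmi.Structure()
    st.name = model.model_id
    mdl = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple, gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        rkey = a.residue_key()
        if rkey not in residues:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
            res.het_flag = "A"
            chains[a.chain_id].add_residue(res)
            residues[rkey] = chains[a.chain_id][-1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.coord)
        atom.occ = 1.0
        atom.b_iso = 0.0
        residues[rkey].add_atom(atom)
    for ch in chains.values():
        mdl.add_chain(ch)
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# sequences and alignment


def chain_sequence(model: Model, chain: str) -> tuple[str, list[tuple[str, int, str]]]:
    """One-letter sequence of a chain plus the residue keys, in file order."""
    seq = []
    keys = []
    seen = set()
    for a in model.atoms:
        if a.chain_id != chain:
            continue
        rkey = a.residue_key()
        if rkey in seen:
            continue
        seen.add(rkey)
        keys.append(rkey)
        seq.append(THREE_TO_ONE.get(a.res_name, "X"))
    return "".join(seq), keys


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # end gaps free: a model chain may cover only part of the target
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # legacy attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def align_sequences(target_seq: str, model_seq: str) -> tuple[float, float, dict[int, int]]:
    """Globally align a model chain to a target chain.

    Returns ``(identity, coverage, mapping)`` where identity is
    matches / aligned columns, coverage is aligned target positions /
    target length, and mapping sends 0-based model positions to 1-based
    target positions.
    """
    aln = _aligner().align(target_seq, model_seq)[0]
    tgt_blocks, mod_blocks = aln.aligned
    matches = 0
    aligned_cols = 0
    mapping: dict[int, int] = {}
    for (ts, te), (ms, me) in zip(tgt_blocks, mod_blocks):
        for k in range(te - ts):
            ti, mi = ts + k, ms + k
            aligned_cols += 1
            if target_seq[ti] == model_seq[mi]:
                matches += 1
            mapping[mi] = ti + 1
    if aligned_cols == 0:
        return 0.0, 0.0, {}
    identity = matches / aligned_cols
    coverage = aligned_cols / len(target_seq)
    return identity, coverage, mapping


def assign_chains(
    model: Model,
    target: TargetSpec,
    identity_min: float = 0.90,
    coverage_min: float = 0.70,
) -> dict[str, tuple[str, dict[int, int]]] | None:
    """Assign model chains to target chain labels.

    Greedy one-to-one assignment by best alignment identity (ties broken by
    model file order, then target label order).  Returns ``None`` when some
    chain cannot be assigned at the identity/coverage thresholds — such a
    model is not a model of the target.
    """
    model_chains = model.chains
    if len(model_chains) > len(target.chain_labels):
        return None
    scored = []
    for ci, mchain in enumerate(model_chains):
        mseq, _ = chain_sequence(model, mchain)
        for li, label in enumerate(target.chain_labels):
            ident, cov, mapping = align_sequences(target.sequences[label], mseq)
            if ident >= identity_min and cov >= coverage_min:
                scored.append((-ident, ci, li, mchain, label, mapping))
    scored.sort()
    assignment: dict[str, tuple[str, dict[int, int]]] = {}
    used_labels: set[str] = set()
    for _negident, _ci, _li, mchain, label, mapping in scored:
        if mchain in assignment or label in used_labels:
            continue
        assignment[mchain] = (label, mapping)
        used_labels.add(label)
    if len(assignment) != len(model_chains):
        return None
    return assignment


# ---------------------------------------------------------------------------
# filtering and renumbering


def filter_ensemble(
    models: Sequence[Model],
    target: TargetSpec,
    contact_fn: Callable[[Model], int],
    identity_min: float = 0.90,
    coverage_min: float = 0.70,
    read_failures: Sequence[ReadFailure] = (),
) -> tuple[list[Model], FilterReport]:
    """Remove models that cannot be consensus-scored.

    ``contact_fn`` maps a renumbered model to its intermolecular contact
    count (supplied by the contact module to avoid a circular dependency).
    Read failures from :func:`read_ensemble` may be passed through so that
    the report covers the whole input set.  Order of kept models is
    preserved.
    """
    report = FilterReport(n_input=len(models) + len(read_failures))
    for f in read_failures:
        report.add(f.reason, f.model_id)
    kept: list[Model] = []
    for model in models:
        if len(model.chains) < 2:
            report.add("single_chain", model.model_id)
            continue
        assignment = assign_chains(model, target, identity_min, coverage_min)
        if assignment is None:
            report.add("sequence_mismatch", model.model_id)
            continue
        renumbered = _apply_assignment(model, target, assignment)
        if contact_fn(renumbered) == 0:
            report.add("zero_contacts", model.model_id)
            continue
        kept.append(model)
        report.kept_ids.append(model.model_id)
    report.check()
    if not kept:
        raise ValueError("no scorable models after filtering")
    return kept, report


def _apply_assignment(
    model: Model,
    target: TargetSpec,
    assignment: dict[str, tuple[str, dict[int, int]]],
) -> Model:
    """Rename chains and renumber residues per a chain assignment.

    Aligned residues get the 1-based target position; unaligned residues
    keep their coordinates but are numbered past the target length and
    excluded from contact consideration.  Insertion codes are flattened.
    """
    new_atoms: list[AtomRecord] = []
    contact_residues: dict[str, set[int]] = {}
    for mchain in model.chains:
        label, mapping = assignment[mchain]
        _seq, keys = chain_sequence(model, mchain)
        pos_of_key = {k: i for i, k in enumerate(keys)}
        L = len(target.sequences[label])
        extra = L
        newnum: dict[tuple, int] = {}
        eligible: set[int] = set()
        for key in keys:
            tpos = mapping.get(pos_of_key[key])
            if tpos is None:
                extra += 1
                newnum[key] = extra
            else:
                newnum[key] = tpos
                eligible.add(tpos)
        contact_residues[label] = eligible
        for a in model.atoms:
            if a.chain_id != mchain:
                continue
            new_atoms.append(
                AtomRecord(
                    chain_id=label,
                    res_seq=newnum[a.residue_key()],
                    icode="",
                    res_name=a.res_name,
                    atom_name=a.atom_name,
                    element=a.element,
                    coord=a.coord,
                )
            )
    return Model(model.model_id, new_atoms, contact_residues=contact_residues)


def renumber_ensemble(
    models: Sequence[Model],
    target: TargetSpec,
    identity_min: float = 0.90,
    coverage_min: float = 0.70,
) -> list[Model]:
    """Consistently renumber an ensemble against the target.

    Corresponding amino acids end up with the same chain identifier and
    residue number in every model — the prerequisite for comparing contact
    maps across models.  Models are expected to have passed
    :func:`filter_ensemble`; a model whose chains can no longer be assigned
    is dropped with a warning.
    """
    out: list[Model] = []
    for model in models:
        assignment = assign_chains(model, target, identity_min, coverage_min)
        if assignment is None:
            warnings.warn(f"model {model.model_id}: unassignable chains, dropped")
            continue
        out.append(_apply_assignment(model, target, assignment))
    return out
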