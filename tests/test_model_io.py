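"""Reading, filtering and renumbering of decoy ensembles."""

import numpy as np
import pytest

from consrank.contacts import compute_contact_map
from consrank.model_io import (
    AtomRecord,
    Model,
    ReadFailure,
    TargetSpec,
    align_sequences,
    chain_sequence,
    filter_ensemble,
    read_model,
    renumber_ensemble,
    write_model,
)
from consrank.synth import SyntheticSpec, generate_ensemble, target_spec


def _pdb_line(serial, name, resname, chain, resseq, x, y, z, element, altloc=" ", occ=1.0):
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


class TestReadModel:
    def test_roundtrip_through_pdb(self, reference_dimer, tmp_path):
        path = tmp_path / "ref.pdb"
        write_model(reference_dimer, path)
        back = read_model(path)
        assert isinstance(back, Model)
        assert back.chains == reference_dimer.chains
        assert len(back.atoms) == len(reference_dimer.atoms)
        np.testing.assert_allclose(
            back.arrays()["coords"], reference_dimer.arrays()["coords"], atol=1e-3
        )

    def test_empty_file_is_reported_not_raised(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_bytes(b"")
        out = read_model(path)
        assert isinstance(out, ReadFailure)
        assert out.reason == "empty"

    def test_split_chain_segments_are_merged(self, tmp_path):
        lines = [
            _pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            _pdb_line(2, "CA", "ALA", "B", 1, 8, 0, 0, "C"),
            _pdb_line(3, "CA", "ALA", "A", 2, 0, 4, 0, "C"),
            "END",
        ]
        path = tmp_path / "split.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_model(path)
        assert isinstance(model, Model)
        assert sorted(model.chains) == ["A", "B"]
        assert model.n_residues("A") == 2

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            _pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C", altloc="A", occ=0.4),
            _pdb_line(2, "CA", "ALA", "A", 1, 9, 9, 9, "C", altloc="B", occ=0.6),
            _pdb_line(3, "CA", "ALA", "B", 1, 4, 0, 0, "C"),
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_model(path)
        ca = [a for a in model.atoms if a.chain_id == "A"][0]
        assert ca.coord == (9.0, 9.0, 9.0)

    def test_hetatm_and_hydrogens_ignored(self, tmp_path):
        lines = [
            _pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            _pdb_line(2, "H", "ALA", "A", 1, 1, 0, 0, "H"),
            "HETATM    3  O   HOH A 100      2.000   0.000   0.000  1.00  0.00           O",
            _pdb_line(4, "CA", "ALA", "B", 1, 4, 0, 0, "C"),
            "END",
        ]
        path = tmp_path / "het.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_model(path)
        assert len(model.atoms) == 2
        assert all(a.element != "H" for a in model.atoms)


class TestAlignment:
    def test_identity_mapping(self):
        ident, cov, mapping = align_sequences("AAAA", "AAAA")
        assert ident == 1.0 and cov == 1.0
        assert mapping == {0: 1, 1: 2, 2: 3, 3: 4}

    def test_partial_coverage(self):
        ident, cov, mapping = align_sequences("A" * 10, "A" * 6)
        assert ident == 1.0
        assert cov == pytest.approx(0.6)

    def test_mismatch_identity(self):
        seq_t = "ACDEFGHIKL"
        seq_m = "ACDEFGHIKV"  # one substitution
        ident, cov, _ = align_sequences(seq_t, seq_m)
        assert ident == pytest.approx(0.9)


def _mutate_chain(model: Model, chain: str, res_name: str) -> Model:
    atoms = [
        AtomRecord(a.chain_id, a.res_seq, a.icode, res_name, a.atom_name, a.element, a.coord)
        if a.chain_id == chain
        else a
        for a in model.atoms
    ]
    return Model(model.model_id + "_mut", atoms)


def _single_chain(model: Model) -> Model:
    return Model("mono", [a for a in model.atoms if a.chain_id == "A"] +
                 [AtomRecord("A", a.res_seq + 100, a.icode, a.res_name, a.atom_name,
                             a.element, a.coord)
                  for a in model.atoms if a.chain_id == "B"])


def _shift_chain(model: Model, chain: str, offset: np.ndarray, new_id: str) -> Model:
    atoms = [
        AtomRecord(a.chain_id, a.res_seq, a.icode, a.res_name, a.atom_name, a.element,
                   tuple(np.asarray(a.coord) + offset))
        if a.chain_id == chain
        else a
        for a in model.atoms
    ]
    return Model(new_id, atoms)


class TestFilterEnsemble:
    @pytest.fixture()
    def contact_fn(self):
        return lambda m: compute_contact_map(m, cutoff=5.0, symmetric=True).M

    def test_rules_and_report_reconcile(self, reference_dimer, default_spec, contact_fn):
        target = target_spec(default_spec)
        good = Model("good", reference_dimer.atoms)
        mono = _single_chain(reference_dimer)
        mutant = _mutate_chain(reference_dimer, "B", "VAL")  # identity 0 on chain B
        apart = _shift_chain(reference_dimer, "B", np.array([200.0, 0, 0]), "apart")
        kept, report = filter_ensemble([good, mono, mutant, apart], target, contact_fn)
        assert [m.model_id for m in kept] == ["good"]
        assert report.discarded["single_chain"] == ["mono"]
        assert report.discarded["sequence_mismatch"] == ["reference_mut"]
        assert report.discarded["zero_contacts"] == ["apart"]
        assert report.n_input == report.n_kept + report.n_discarded

    def test_idempotent_on_kept(self, small_ensemble):
        spec, models, truth, target = small_ensemble
        fn = lambda m: compute_contact_map(m, cutoff=5.0, symmetric=True).M
        kept, _ = filter_ensemble(models, target, fn)
        kept2, report2 = filter_ensemble(kept, target, fn)
        assert [m.model_id for m in kept2] == [m.model_id for m in kept]
        assert report2.n_discarded == 0

    def test_all_discarded_raises(self, reference_dimer, default_spec, contact_fn):
        target = target_spec(default_spec)
        with pytest.raises(ValueError, match="no scorable models"):
            filter_ensemble([_single_chain(reference_dimer)], target, contact_fn)


class TestRenumbering:
    def test_offset_numbering_is_restored(self, reference_dimer, default_spec):
        target = target_spec(default_spec)
        shifted = Model(
            "shifted",
            [
                AtomRecord(a.chain_id, a.res_seq + 10, a.icode, a.res_name,
                           a.atom_name, a.element, a.coord)
                for a in reference_dimer.atoms
            ],
        )
        (ren,) = renumber_ensemble([shifted], target)
        L = default_spec.n_residues_per_chain
        for chain in ren.chains:
            nums = sorted({a.res_seq for a in ren.atoms if a.chain_id == chain})
            assert nums == list(range(1, L + 1))

    def test_preserves_atom_count_and_coordinates(self, small_ensemble):
        spec, models, truth, target = small_ensemble
        ren = renumber_ensemble(models[:5], target)
        for before, after in zip(models[:5], ren):
            assert len(before.atoms) == len(after.atoms)
            np.testing.assert_array_equal(
                before.arrays()["coords"], after.arrays()["coords"]
            )

    def test_swapped_chain_labels_canonicalized(self, reference_dimer, default_spec):
        target = target_spec(default_spec)
        relabeled = Model(
            "swap",
            [
                AtomRecord("B" if a.chain_id == "A" else "A", a.res_seq, a.icode,
                           a.res_name, a.atom_name, a.element, a.coord)
                for a in reference_dimer.atoms
            ],
        )
        (ren,) = renumber_ensemble([relabeled], target)
        assert sorted(ren.chains) == ["A", "B"]
        # symmetrized contact map is invariant to the relabeling
        ref_map = compute_contact_map(reference_dimer, symmetric=True)
        swap_map = compute_contact_map(ren, symmetric=True)
        assert ref_map.contacts == swap_map.contacts


class TestTargetSpec:
    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            TargetSpec(sequences={"A": "AZ1"})

    def test_partition_default_first_vs_rest(self):
        t = TargetSpec(sequences={"A": "AAA", "B": "AAA", "C": "AAA"})
        assert t.partition() == (("A",), ("B", "C"))

    def test_fasta_roundtrip(self, tmp_path):
        p = tmp_path / "t.fasta"
        p.write_text(">A\nAAAA\n>B\nAAAA\n")
        t = TargetSpec.from_fasta(p)
        assert t.sequences == {"A": "AAAA", "B": "AAAA"}
        assert t.is_symmetric_pair()


def test_generated_ensemble_passes_filter_without_discards(small_ensemble):
    spec, models, truth, target = small_ensemble
    fn = lambda m: compute_contact_map(m, cutoff=5.0, symmetric=True).M
    kept, report = filter_ensemble(models, target, fn)
    assert report.n_discarded == 0
    assert len(kept) == spec.n_models
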