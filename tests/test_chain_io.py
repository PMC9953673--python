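"""Data model invariants and trajectory/sequence round trips."""

import numpy as np
import pytest

from polyion.chain import ChainSpec, Ensemble, Frame, IonRecord, SaltSpec
from polyion.io import (
    ParseError,
    StructuralError,
    read_ensemble,
    read_fasta,
    write_ensemble,
)

from conftest import random_ensemble


class TestDataModel:
    def test_chain_spec_invariants(self):
        with pytest.raises(ValueError):
            ChainSpec(1, ("E",), (-1.0,))
        with pytest.raises(ValueError):
            ChainSpec(3, ("E", "E"), (-1.0, -1.0, -1.0))
        with pytest.raises(ValueError):
            ChainSpec(2, ("E", "E"), (-1.0, -1.0), bond_length=0.0)

    def test_ion_record_invariants(self):
        with pytest.raises(ValueError):
            IonRecord("NA", 0, (0, 0, 0), 2.3)
        with pytest.raises(ValueError):
            IonRecord("NA", 1, (0, 0, np.nan), 2.3)

    def test_salt_spec_requires_neutralization_at_zero_salt(self):
        spec = ChainSpec(2, ("E", "E"), (-1.0, -1.0))
        salt = SaltSpec(concentration=0.0, neutralize_chain=False)
        with pytest.raises(ValueError):
            salt.validate_for_chain(spec)

    def test_ensemble_rejects_inconsistent_frames(self, three_bead_spec):
        f1 = Frame(chain_coords=np.zeros((3, 3)), frame_index=0)
        f2 = Frame(chain_coords=np.zeros((2, 3)), frame_index=1)
        with pytest.raises(ValueError, match="beads"):
            Ensemble(spec=three_bead_spec, frames=[f1, f2])
        f3 = Frame(chain_coords=np.zeros((3, 3)), frame_index=0)
        with pytest.raises(ValueError, match="increasing"):
            Ensemble(spec=three_bead_spec, frames=[f1, f3])


class TestPDB:
    def test_round_trip_preserves_coordinates_to_pdb_precision(
            self, small_ensemble, tmp_path):
        path = tmp_path / "traj.pdb"
        write_ensemble(small_ensemble, path)
        back = read_ensemble(path)
        assert back.n_frames == small_ensemble.n_frames
        np.testing.assert_allclose(back.coordinates(),
                                   small_ensemble.coordinates(), atol=1.5e-3)

    def test_model_and_atom_counts(self, small_ensemble, tmp_path):
        path = tmp_path / "traj.pdb"
        write_ensemble(small_ensemble, path)
        text = path.read_text()
        assert text.count("MODEL") == 2
        assert sum(line.startswith("ATOM") for line in text.splitlines()) == 6
        assert sum(line.startswith("HETATM") for line in text.splitlines()) == 2

    def test_inconsistent_model_sizes_raise_structural_error(self, tmp_path):
        pdb = (
            "MODEL        1\n"
            "ATOM      1  CA  GLU A   1      10.000  10.000  10.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLU A   2      13.800  10.000  10.000  1.00  0.00           C\n"
            "ATOM      3  CA  GLU A   3      17.600  10.000  10.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  GLU A   1      10.000  10.000  10.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLU A   2      13.800  10.000  10.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        path = tmp_path / "bad.pdb"
        path.write_text(pdb)
        with pytest.raises(StructuralError):
            read_ensemble(path)

    def test_malformed_coordinates_name_the_line(self, tmp_path):
        pdb = (
            "MODEL        1\n"
            "ATOM      1  CA  GLU A   1      10.000  xxxxxx  10.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        path = tmp_path / "bad.pdb"
        path.write_text(pdb)
        with pytest.raises(ParseError, match="line 2"):
            read_ensemble(path)


class TestColumnar:
    def test_round_trip_is_identity(self, small_ensemble, tmp_path):
        path = tmp_path / "traj.tsv"
        write_ensemble(small_ensemble, path, format_hint="columnar")
        back = read_ensemble(path, format_hint="columnar")
        np.testing.assert_allclose(back.coordinates(),
                                   small_ensemble.coordinates(), atol=1e-6)
        assert back.spec.residue_labels == small_ensemble.spec.residue_labels
        assert back.spec.bead_charge == small_ensemble.spec.bead_charge
        ion0 = back.frames[0].ions[0]
        assert ion0.species_label == "NA" and ion0.valence == 1

    @pytest.mark.parametrize("case", range(5))
    def test_round_trip_random_ensembles(self, case, tmp_path):
        rng = np.random.default_rng(case)
        ens = random_ensemble(rng, n_res=int(rng.integers(2, 8)),
                              n_frames=int(rng.integers(1, 6)),
                              n_ions=int(rng.integers(0, 4)))
        path = tmp_path / "t.tsv"
        write_ensemble(ens, path, format_hint="columnar")
        back = read_ensemble(path, format_hint="columnar")
        assert back.n_frames == ens.n_frames
        np.testing.assert_allclose(back.coordinates(), ens.coordinates(),
                                   atol=1e-6)

    def test_bad_magic_raises_parse_error(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("not a trajectory\n")
        with pytest.raises(ParseError, match="line 1"):
            read_ensemble(path, format_hint="columnar")


class TestFasta:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "p.fasta"
        p.write_text(">p1\nDDEE\n>p2\nKKRR\n")
        assert read_fasta(p) == [("p1", "DDEE"), ("p2", "KKRR")]

    def test_whitespace_stripped_and_uppercased(self, tmp_path):
        p = tmp_path / "p.fasta"
        p.write_text(">p1\ndd ee\n")
        assert read_fasta(p) == [("p1", "DDEE")]

    def test_non_alphabetic_characters_rejected(self, tmp_path):
        p = tmp_path / "p.fasta"
        p.write_text(">p1\nDD3EE\n")
        with pytest.raises(ParseError, match="3"):
            read_fasta(p)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "p.fasta"
        p.write_text("")
        assert read_fasta(p) == []
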