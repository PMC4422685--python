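import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apehkit import (
    DomainPartition,
    PeptideSpec,
    compute_dihedral,
    extract_sequence,
    make_peptide,
    ramachandran_summary,
    read_structure,
    write_structure,
)
from apehkit.errors import FormatError, GeometryError, RangeError
from apehkit.structures import backbone_dihedrals


class TestComputeDihedral:
    @pytest.mark.parametrize(
        "pts, expected",
        [
            # direct evaluation of the atan2 convention
            ((((1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1))), -90.0),
            # coplanar trans arrangement
            ((((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))), 180.0),
            # coplanar cis arrangement
            ((((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))), 0.0),
        ],
    )
    def test_reference_angles(self, pts, expected):
        assert compute_dihedral(*pts) == pytest.approx(expected, abs=1e-9)

    def test_range_excludes_minus_180(self):
        assert compute_dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == 180.0

    def test_degenerate_geometry_raises(self):
        with pytest.raises(GeometryError):
            compute_dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(GeometryError):  # collinear b1, b2
            compute_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0))

    @given(st.lists(st.floats(-10, 10), min_size=12, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_reversal_invariance_and_mirror_antisymmetry(self, flat):
        # a torsion angle keeps its value and sign viewed from either end of
        # the chain; reflecting the points negates it
        p = [np.array(flat[i:i + 3]) for i in (0, 3, 6, 9)]
        try:
            fwd = compute_dihedral(*p)
            rev = compute_dihedral(*reversed(p))
            mirrored = compute_dihedral(*(q * np.array([1.0, 1.0, -1.0]) for q in p))
        except GeometryError:
            return
        assert math.isclose(fwd, rev, abs_tol=1e-6)
        assert math.isclose((fwd + mirrored) % 360.0, 0.0, abs_tol=1e-6) or \
            math.isclose((fwd + mirrored) % 360.0, 360.0, abs_tol=1e-6)


class TestPDBRoundTrip:
    def test_coordinates_and_identity_preserved(self, bridged_toy, tmp_path):
        structure, _, _ = bridged_toy
        path = tmp_path / "toy.pdb"
        write_structure(structure, path)
        again = read_structure(path)
        assert [(r.number, r.name3) for r in again.residues] == \
            [(r.number, r.name3) for r in structure.residues]
        c1, idx1 = structure.atom_array()
        c2, idx2 = again.atom_array()
        assert [a.name for _, a in idx1] == [a.name for _, a in idx2]
        assert np.abs(c1 - c2).max() < 1e-3  # PDB coordinate precision

    def test_single_atom_record(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "END\n"
        )
        s = read_structure(path)
        assert len(s.residues) == 1
        assert len(s.residues[0].atoms) == 1
        assert np.allclose(s.residues[0].atoms[0].coords, [1.0, 2.0, 3.0])

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(FormatError):
            read_structure(path)

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_structure(tmp_path / "nope.pdb")


class TestExtractSequence:
    def test_tripeptide(self):
        s = make_peptide(PeptideSpec("GAD"))
        assert extract_sequence(s) == "GAD"

    def test_region_slice_of_string(self):
        assert extract_sequence("ABCDEFGHIJ", region=(2, 4)) == "BCD"

    def test_region_slice_of_structure(self, helix10):
        assert extract_sequence(helix10, region=(3, 5)) == "AAA"

    def test_region_outside_numbering(self, helix10):
        with pytest.raises(RangeError):
            extract_sequence(helix10, region=(5, 40))
        with pytest.raises(RangeError):
            extract_sequence("ABC", region=(0, 2))


class TestRamachandran:
    def test_ideal_helix_all_core(self, helix10):
        summary = ramachandran_summary(helix10)
        assert summary.fraction_allowed == 1.0
        # interior residues re-measure the generator's dihedrals
        for _, phi, psi in summary.per_residue[1:-1]:
            assert phi == pytest.approx(-57.0, abs=1e-3)
            assert psi == pytest.approx(-47.0, abs=1e-3)

    def test_termini_excluded(self, helix10):
        summary = ramachandran_summary(helix10)
        assert summary.n_classified == len(helix10) - 2

    def test_two_residues_warn_and_nan(self):
        s = make_peptide(PeptideSpec("AA"))
        with pytest.warns(UserWarning):
            summary = ramachandran_summary(s)
        assert math.isnan(summary.fraction_allowed)

    def test_dihedrals_match_generator_inputs(self):
        rng = np.random.default_rng(7)
        phi = list(rng.uniform(-170, -50, size=8))
        psi = list(rng.uniform(-60, 150, size=8))
        s = make_peptide(PeptideSpec("A" * 8, phi=phi, psi=psi))
        for i, (_, got_phi, got_psi) in enumerate(backbone_dihedrals(s)):
            if got_phi is not None:
                assert got_phi == pytest.approx(phi[i], abs=1e-3)
            if got_psi is not None:
                assert got_psi == pytest.approx(psi[i], abs=1e-3)


class TestDomainPartition:
    def test_from_string_and_classify(self):
        p = DomainPartition.from_string("x", "Nter:1-450,linker:451-460,Cter:461-729")
        assert p.classify(10) == "N-ter"
        assert p.classify(455) == "linker"
        assert p.classify(600) == "C-ter"
        assert p.classify(1000) is None

    def test_implicit_linker_from_bounds(self):
        p = DomainPartition.from_bounds("x", (1, 450), (461, 729))
        assert p.region("linker").start == 451
        assert p.region("linker").end == 460

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            DomainPartition.from_string("x", "Nter:1-100,Cter:90-200")
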