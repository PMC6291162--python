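"""Ligand-contact annotation: distance rule, invariances, exports."""

import numpy as np
import pytest

from ralascope.structure_contacts import (
    LigandAbsentError,
    RegionAnnotation,
    StructureFormatError,
    contact_residues,
    export_region,
    read_region_list,
    read_structure,
    region_fraction,
)
from ralascope.synthetic_data import SimulationConfig, simulate_structure


def _pdb_line(record, serial, name, resname, chain, resid, x, y, z,
              occ=1.00, altloc=" "):
    element = name[0]
    return (
        f"{record:<6s}{serial:5d} {name:<4s}{altloc}{resname:>3s} {chain}"
        f"{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.00:6.2f}"
        f"          {element:>2s}\n"
    )


@pytest.fixture()
def boundary_structure(tmp_path):
    """Three residues: one CA at 1.4 A from the ligand atom, one at 1.6 A,
    one far away."""
    path = tmp_path / "boundary.pdb"
    lines = [
        _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 1.4, 0.0),
        _pdb_line("ATOM", 2, "CA", "GLY", "A", 2, 0.0, -1.6, 0.0),
        _pdb_line("ATOM", 3, "CA", "GLY", "A", 3, 30.0, 0.0, 0.0),
        _pdb_line("HETATM", 4, "PA", "GDP", "B", 301, 0.0, 0.0, 0.0),
        "END\n",
    ]
    path.write_text("".join(lines), encoding="utf-8")
    return path


class TestReadStructure:
    def test_synthetic_fixture_parses(self, boundary_structure):
        model = read_structure(boundary_structure)
        assert len(model.protein_atoms) == 3
        assert len(model.ligand_atoms("GDP")) == 1

    def test_waters_are_not_ligands(self, tmp_path):
        path = tmp_path / "waters.pdb"
        path.write_text(
            _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0)
            + _pdb_line("HETATM", 2, "O", "HOH", "B", 301, 1.0, 0.0, 0.0)
            + "END\n",
            encoding="utf-8",
        )
        model = read_structure(path)
        with pytest.raises(LigandAbsentError):
            contact_residues(model, "GDP", 1.5)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n", encoding="utf-8")
        with pytest.raises(StructureFormatError):
            read_structure(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(StructureFormatError):
            read_structure(tmp_path / "nope.pdb")

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        # one residue with A/B altlocs of its CA: expect a single atom,
        # the higher-occupancy B location
        path = tmp_path / "altloc.pdb"
        lines = [
            _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0,
                      occ=0.3, altloc="A"),
            _pdb_line("ATOM", 2, "CA", "GLY", "A", 1, 5.0, 0.0, 0.0,
                      occ=0.7, altloc="B"),
            _pdb_line("ATOM", 3, "CA", "GLY", "A", 2, 10.0, 0.0, 0.0),
            _pdb_line("HETATM", 4, "PA", "GDP", "B", 301, 20.0, 0.0, 0.0),
            "END\n",
        ]
        path.write_text("".join(lines), encoding="utf-8")
        model = read_structure(path)
        assert len(model.protein_atoms) == 2  # manual count: 1 CA kept + res 2
        kept = [a for a in model.protein_atoms if a.residue_index == 1]
        assert len(kept) == 1 and kept[0].x == pytest.approx(5.0)


class TestContactRule:
    def test_boundary_is_inclusive_at_threshold(self, boundary_structure):
        model = read_structure(boundary_structure)
        region = contact_residues(model, "GDP", 1.5, protein_length=3)
        assert region.sorted_residues == [1]
        # at 1.6 the second residue enters (<= comparison)
        region = contact_residues(model, "GDP", 1.6, protein_length=3)
        assert region.sorted_residues == [1, 2]

    def test_zero_threshold_rejected(self, boundary_structure):
        model = read_structure(boundary_structure)
        with pytest.raises(ValueError):
            contact_residues(model, "GDP", 0.0)

    def test_declared_contacts_recovered(self, tmp_path):
        cfg = SimulationConfig(seed=11)
        path, truth = simulate_structure(cfg, 10, {3, 4, 7}, 2.0,
                                         tmp_path / "s.pdb")
        model = read_structure(path)
        region = contact_residues(model, "GDP", 2.0, protein_length=10)
        assert set(region.residues) == set(truth)

    def test_threshold_monotonicity(self, tmp_path):
        cfg = SimulationConfig(seed=5)
        path, _ = simulate_structure(cfg, 12, {2, 6, 9}, 2.5, tmp_path / "s.pdb")
        model = read_structure(path)
        previous = set()
        for t in (0.5, 1.0, 1.5, 2.0, 2.5, 3.5, 5.0):
            current = set(contact_residues(model, "GDP", t,
                                           protein_length=12).residues)
            assert previous <= current
            previous = current

    def test_rigid_motion_invariance(self, tmp_path):
        """A global rotation+translation must not change the contact set."""
        cfg = SimulationConfig(seed=23)
        path, truth = simulate_structure(cfg, 10, {1, 5}, 2.0, tmp_path / "a.pdb")
        model = read_structure(path)
        rng = np.random.default_rng(99)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        shift = rng.uniform(-50, 50, size=3)
        moved = []
        for atom in model.atoms:
            x, y, z = (np.array(atom.xyz) @ q.T) + shift
            moved.append(
                type(atom)(atom.chain_id, atom.residue_index, atom.residue_name,
                           atom.atom_name, atom.element, x, y, z, atom.is_hetero)
            )
        model_moved = type(model)(model.structure_id, moved, model.ligand_codes)
        before = contact_residues(model, "GDP", 2.0, protein_length=10)
        after = contact_residues(model_moved, "GDP", 2.0, protein_length=10)
        assert set(before.residues) == set(after.residues)


class TestRegionOutputs:
    def test_region_fraction_paper_geometry(self):
        region = RegionAnnotation(206, frozenset(range(1, 25)))
        assert region_fraction(region) == 11.7

    def test_region_fraction_edge_cases(self):
        assert region_fraction(RegionAnnotation(206, frozenset())) == 0.0
        assert region_fraction(
            RegionAnnotation(206, frozenset(range(1, 207)))) == 100.0

    def test_out_of_range_residues_rejected(self):
        with pytest.raises(ValueError):
            RegionAnnotation(10, frozenset({11}))

    @pytest.mark.parametrize(
        "residues, expected_bed",
        [
            ({25}, [("prot", 24, 25)]),
            (set(range(1, 207)), [("prot", 0, 206)]),
            ({3, 4, 7}, [("prot", 2, 4), ("prot", 6, 7)]),
        ],
    )
    def test_bed_export_runs(self, tmp_path, residues, expected_bed):
        region = RegionAnnotation(206, frozenset(residues))
        out = tmp_path / "region.bed"
        export_region(region, out, format="BED", gene_symbol="prot")
        rows = [
            (f[0], int(f[1]), int(f[2]))
            for f in (ln.split("\t") for ln in out.read_text().splitlines())
        ]
        assert rows == expected_bed

    def test_residue_list_roundtrip(self, tmp_path):
        region = RegionAnnotation(206, frozenset({5, 6, 90}))
        out = tmp_path / "region.txt"
        export_region(region, out, format="residue-list")
        again = read_region_list(out, 206)
        assert set(again.residues) == set(region.residues)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_region(RegionAnnotation(10, frozenset({1})),
                          tmp_path / "x", format="gff")
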