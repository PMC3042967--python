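import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confens import (
    Conformer,
    MoleculeGraph,
    SdfParseError,
    build_template,
    effective_rotor_count,
    filter_ligand_set,
    fragment_sample_count,
    perceive,
    read_sdf,
    write_sdf,
)
from confens.molgraph import (
    REASON_TOO_FLEXIBLE,
    REASON_TOO_LARGE,
    REASON_TOO_SMALL,
)

from conftest import ETHANE_SDF, chain_mol, random_molecule


class TestReadSdf:
    def test_single_record_identity_parse(self, ethane_sdf):
        records = read_sdf(ethane_sdf)
        assert len(records) == 1
        mol, confs = records[0]
        assert mol.name == "ethane"
        assert len(confs) == 1
        assert len(mol.atoms) == 8
        assert mol.n_heavy == 2
        assert confs[0].coords.shape == (8, 3)

    def test_consecutive_identical_records_group_into_ensemble(self):
        text = ETHANE_SDF * 3
        records = read_sdf(io.StringIO(text))
        assert len(records) == 1
        assert len(records[0][1]) == 3

    def test_different_names_do_not_group(self):
        text = ETHANE_SDF + ETHANE_SDF.replace("ethane", "other")
        records = read_sdf(io.StringIO(text))
        assert len(records) == 2

    def test_bond_out_of_range_names_record(self):
        bad = ETHANE_SDF.replace("  2  8  1  0", "  2 99  1  0")
        with pytest.raises(SdfParseError, match="record 1"):
            read_sdf(io.StringIO(bad))

    def test_malformed_counts_line(self):
        bad = ETHANE_SDF.replace("  8  7  0", "  x  7  0")
        with pytest.raises(SdfParseError, match="counts"):
            read_sdf(io.StringIO(bad))

    def test_v3000_rejected(self):
        bad = ETHANE_SDF.replace("V2000", "V3000")
        with pytest.raises(SdfParseError, match="V3000"):
            read_sdf(io.StringIO(bad))

    def test_multi_fragment_record_rejected(self):
        # drop the C-C bond: two disconnected CH3 fragments
        bad = ETHANE_SDF.replace("  8  7  0", "  8  6  0").replace("  1  2  1  0\n", "")
        with pytest.raises(SdfParseError, match="fragment"):
            read_sdf(io.StringIO(bad))

    def test_energy_tag_populates_conformer_energy(self):
        text = ETHANE_SDF.replace("M  END\n", "M  END\n> <ENERGY>\n1.25\n\n")
        records = read_sdf(io.StringIO(text))
        assert records[0][1][0].energy == pytest.approx(1.25)

    def test_roundtrip_preserves_graph_and_coords(self, ethane_sdf):
        records = read_sdf(ethane_sdf)
        buf = io.StringIO()
        write_sdf(records, buf)
        buf.seek(0)
        again = read_sdf(buf)
        assert again[0][0] == records[0][0]
        np.testing.assert_allclose(
            again[0][1][0].coords, records[0][1][0].coords, atol=5e-5
        )


class TestPerception:
    def test_benzene(self, benzene):
        _, _, p = benzene
        assert len(p.rings) == 1
        assert len(p.aromatic_atoms) == 6
        assert p.n_nara == 0
        assert p.n_r == 0

    def test_cyclohexane(self, cyclohexane):
        _, _, p = cyclohexane
        assert len(p.rings) == 1
        assert len(p.aromatic_atoms) == 0
        assert p.n_nara == 6
        assert p.n_r == 0

    def test_pentane_rotors_exclude_terminal_bonds(self):
        p = perceive(chain_mol(5))
        assert p.rotatable_bonds == {(1, 2), (2, 3)}

    def test_amide_bond_excluded_by_default(self):
        # N-methylacetamide heavy atoms: C-C(=O)-N-C
        mol = MoleculeGraph(
            atoms=(("C", 0), ("C", 0), ("O", 0), ("N", 0), ("C", 0)),
            bonds=((0, 1, 1), (1, 2, 2), (1, 3, 1), (3, 4, 1)),
            name="amide",
        )
        assert (1, 3) not in perceive(mol).rotatable_bonds
        assert (1, 3) in perceive(mol, include_amide_rotors=True).rotatable_bonds

    def test_perception_invariant_under_relabeling(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            mol = random_molecule(rng, int(rng.integers(3, 9)))
            p = perceive(mol)
            perm = rng.permutation(len(mol.atoms))
            inv = np.argsort(perm)
            atoms = tuple(mol.atoms[inv[k]] for k in range(len(mol.atoms)))
            bonds = tuple((int(perm[i]), int(perm[j]), o) for i, j, o in mol.bonds)
            q = perceive(MoleculeGraph(atoms=atoms, bonds=bonds, name="perm"))
            assert (p.n_r, p.n_nara, len(p.rings)) == (q.n_r, q.n_nara, len(q.rings))


class TestDescriptors:
    @pytest.mark.parametrize(
        "template,n_r,n_nara,n_er",
        [
            ("phenyl_chain(0)", 0, 0, 0.0),  # benzene: aromatic, rigid
            ("ring(6)", 0, 6, 1.2),  # cyclohexane: pure ring flexibility
            ("alkane_chain(4)", 1, 0, 1.0),  # n-butane: one rotor
            ("alkane_chain(9)", 6, 0, 6.0),
            ("fused_decalin", 0, 10, 2.0),
        ],
    )
    def test_effective_rotor_count(self, template, n_r, n_nara, n_er):
        mol, _ = build_template(template)
        d = effective_rotor_count(perceive(mol))
        assert d.n_r == n_r
        assert d.n_nara == n_nara
        assert d.n_er == pytest.approx(n_er, abs=1e-12)

    @given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=1000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_effective_rotor_identity_property(self, n_atoms, seed):
        rng = np.random.default_rng(seed)
        mol = random_molecule(rng, n_atoms)
        d = effective_rotor_count(perceive(mol))
        assert d.n_er == d.n_r + d.n_nara / 5
        assert d.n_er >= d.n_r >= 0
        # n_er is whole exactly when n_nara is a multiple of 5
        assert (d.n_er == int(d.n_er)) == (d.n_nara % 5 == 0)


class TestFragmentSampleCount:
    def test_no_junction_atoms(self, cyclohexane):
        _, _, p = cyclohexane
        assert fragment_sample_count(p, startfact=20) == 10

    def test_fused_bicycle_has_two_three_ring_bond_atoms(self):
        mol, _ = build_template("fused_decalin")
        assert fragment_sample_count(perceive(mol), startfact=20) == 50

    def test_spiro_atom_clamps_to_one_with_warning(self):
        # spiro[4.4]nonane: two 5-rings sharing one atom (4 ring bonds)
        atoms = tuple(("C", 0) for _ in range(9))
        bonds = (
            (0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 0, 1),
            (4, 5, 1), (5, 6, 1), (6, 7, 1), (7, 8, 1), (8, 4, 1),
        )
        p = perceive(MoleculeGraph(atoms=atoms, bonds=bonds, name="spiro"))
        with pytest.warns(UserWarning, match="clamped"):
            assert fragment_sample_count(p, startfact=20) == 1

    def test_startfact_must_be_positive(self, cyclohexane):
        with pytest.raises(ValueError):
            fragment_sample_count(cyclohexane[2], startfact=0)


class TestFilterLigandSet:
    def _record(self, mol):
        return (mol, [Conformer(coords=np.zeros((len(mol.atoms), 3)))])

    def test_size_and_flexibility_bounds(self):
        methane = MoleculeGraph(
            atoms=(("C", 0), ("H", 0)), bonds=((0, 1, 1),), name="methane-ish"
        )
        big = chain_mol(51, name="c51")
        eicosane = chain_mol(20, name="c20")  # 17 rotatable bonds
        ok = chain_mol(10, name="c10")
        kept, rejected = filter_ligand_set(
            [self._record(m) for m in (methane, big, eicosane, ok)]
        )
        assert [r[0][0].name for r in rejected] == ["methane-ish", "c51", "c20"]
        assert [reason for _, reason in rejected] == [
            REASON_TOO_SMALL,
            REASON_TOO_LARGE,
            REASON_TOO_FLEXIBLE,
        ]
        assert [m.name for m, _ in kept] == ["c10"]

    def test_filter_is_idempotent(self):
        records = [self._record(chain_mol(n, name=f"c{n}")) for n in (2, 5, 10, 16)]
        kept, _ = filter_ligand_set(records)
        kept2, rejected2 = filter_ligand_set(kept)
        assert kept2 == kept
        assert rejected2 == []
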