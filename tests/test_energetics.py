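import math
from collections import deque

import numpy as np
import pytest

from ppihotspots.energetics import (
    AtomParams,
    ForceFieldParams,
    SCALE_ELE_14,
    SCALE_VDW_14,
    build_extended_reference,
    pair_nonbonded,
    read_energy_table,
    relax_clashes,
    residue_gas_energy,
    write_energy_table,
)
from ppihotspots.residues import extended_template, heavy_atoms, residue_bonds
from ppihotspots.structure import AtomRecord, ProteinStructure, Residue, parse_structure
from ppihotspots.features import make_synthetic_structure
from conftest import rotation_matrix, transform_structure

PARAMS = ForceFieldParams.default()


def template_structure(aa="ALA", chain="A", number=1):
    coords = extended_template(aa)
    atoms = [
        AtomRecord(i + 1, name, "S" if name.startswith("S") else name[0], pos)
        for i, (name, pos) in enumerate(coords.items())
    ]
    return ProteinStructure("tmpl", [Residue(chain, number, "", aa, atoms)])


class TestPairNonbonded:
    def test_coulomb_closed_form(self):
        plus = AtomParams(charge=1.0, rmin_half=1.9, epsilon=0.1)
        minus = AtomParams(charge=-1.0, rmin_half=1.9, epsilon=0.1)
        _, ele = pair_nonbonded([0, 0, 0], [3.320636, 0, 0], plus, minus)
        assert ele == pytest.approx(-100.0, abs=1e-6)

    def test_lj_minimum_is_minus_epsilon(self):
        a = AtomParams(charge=0.0, rmin_half=1.9, epsilon=0.09)
        b = AtomParams(charge=0.0, rmin_half=1.7, epsilon=0.16)
        rmin = 1.9 + 1.7
        vdw, _ = pair_nonbonded([0, 0, 0], [rmin, 0, 0], a, b)
        assert vdw == pytest.approx(-math.sqrt(0.09 * 0.16), rel=1e-12)

    def test_long_range_decay(self):
        a = AtomParams(charge=0.05, rmin_half=1.9, epsilon=0.1)
        vdw, ele = pair_nonbonded([0, 0, 0], [1000.0, 0, 0], a, a)
        assert abs(vdw) < 1e-3 and abs(ele) < 1e-3

    def test_zero_distance_raises(self):
        a = AtomParams(charge=0.0, rmin_half=1.9, epsilon=0.1)
        with pytest.raises(ValueError, match="zero"):
            pair_nonbonded([0, 0, 0], [0, 0, 0], a, a)


class TestExtendedReference:
    @pytest.mark.parametrize("aa", ["GLY", "ALA", "LYS", "PHE", "TRP"])
    def test_deterministic_and_finite(self, aa):
        e1 = build_extended_reference(aa, PARAMS)
        e2 = build_extended_reference(aa, PARAMS)
        assert e1 == e2
        assert math.isfinite(e1)

    @pytest.mark.parametrize("aa", ["ALA", "SER", "LEU", "GLU", "ARG"])
    def test_template_structure_scores_zero(self, aa):
        decomp = residue_gas_energy(template_structure(aa), PARAMS)
        key = ("A", 1, "")
        assert decomp.e_int[key] == pytest.approx(0.0, abs=1e-10)
        assert decomp.e_vdw[key] == 0.0
        assert decomp.e_ele[key] == 0.0
        assert not decomp.incomplete

    def test_every_residue_type_parameterized(self):
        for aa in heavy_atoms.__globals__["SIDE_BONDS"]:
            for name in heavy_atoms(aa):
                assert PARAMS.has(aa, name)


def brute_force_inter_energy(structure, params):
    """Independent all-pairs oracle with its own exclusion bookkeeping."""
    atoms = []
    for ri, res in enumerate(structure.residues):
        for a in res.atoms:
            if a.element != "H" and params.has(res.aa, a.name):
                atoms.append((ri, a.name, a.position, params.lookup(res.aa, a.name)))
    # bond list rebuilt here from the published topology
    bonds = set()
    name_to_idx = {(ri, n): k for k, (ri, n, _, _) in enumerate(atoms)}
    for ri, res in enumerate(structure.residues):
        for a, b in residue_bonds(res.aa):
            if (ri, a) in name_to_idx and (ri, b) in name_to_idx:
                bonds.add(frozenset((name_to_idx[(ri, a)], name_to_idx[(ri, b)])))
        if ri + 1 < len(structure.residues):
            nxt = structure.residues[ri + 1]
            if res.chain == nxt.chain and (ri, "C") in name_to_idx and (ri + 1, "N") in name_to_idx:
                d = np.linalg.norm(res.atom("C").position - nxt.atom("N").position)
                if d <= 1.9:
                    bonds.add(frozenset((name_to_idx[(ri, "C")], name_to_idx[(ri + 1, "N")])))
    adj = {k: set() for k in range(len(atoms))}
    for b in bonds:
        i, j = tuple(b)
        adj[i].add(j)
        adj[j].add(i)

    def path(i, j):
        seen = {i: 0}
        q = deque([i])
        while q:
            u = q.popleft()
            if seen[u] >= 4:
                continue
            for v in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + 1
                    q.append(v)
        return seen.get(j, 99)

    total_vdw = total_ele = 0.0
    per_res_vdw = {r.key: 0.0 for r in structure.residues}
    per_res_ele = {r.key: 0.0 for r in structure.residues}
    keys = [r.key for r in structure.residues]
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if atoms[i][0] == atoms[j][0]:
                continue
            d = path(i, j)
            if d <= 2:
                continue
            sv, se = (SCALE_VDW_14, SCALE_ELE_14) if d == 3 else (1.0, 1.0)
            vdw, ele = pair_nonbonded(atoms[i][2], atoms[j][2], atoms[i][3], atoms[j][3])
            total_vdw += sv * vdw
            total_ele += se * ele
            for ri in (atoms[i][0], atoms[j][0]):
                per_res_vdw[keys[ri]] += 0.5 * sv * vdw
                per_res_ele[keys[ri]] += 0.5 * se * ele
    return total_vdw + total_ele, per_res_vdw, per_res_ele


class TestDecomposition:
    @pytest.fixture
    def dipeptide(self):
        pdb = make_synthetic_structure("AA", "strand", seed=4)
        return parse_structure(pdb, "A")

    def test_matches_bruteforce_oracle(self, dipeptide):
        decomp = residue_gas_energy(dipeptide, PARAMS)
        total, per_vdw, per_ele = brute_force_inter_energy(dipeptide, PARAMS)
        assert decomp.total_inter() == pytest.approx(total, abs=1e-8)
        for key in per_vdw:
            assert decomp.e_vdw[key] == pytest.approx(per_vdw[key], abs=1e-8)
            assert decomp.e_ele[key] == pytest.approx(per_ele[key], abs=1e-8)

    def test_halfsplit_conservation_larger_chain(self):
        st = parse_structure(make_synthetic_structure("ASSAGA", "helix", seed=9), "A")
        decomp = residue_gas_energy(st, PARAMS)
        total, _, _ = brute_force_inter_energy(st, PARAMS)
        assert decomp.total_inter() == pytest.approx(total, rel=1e-10, abs=1e-8)

    def test_rigid_motion_invariance(self, dipeptide):
        R = rotation_matrix([0.2, 1.0, 0.7], 1.3)
        moved = transform_structure(dipeptide, R, np.array([3.0, -8.0, 1.0]))
        d1 = residue_gas_energy(dipeptide, PARAMS)
        d2 = residue_gas_energy(moved, PARAMS)
        for key in d1.e_int:
            assert d2.e_int[key] == pytest.approx(d1.e_int[key], abs=1e-8)
            assert d2.e_vdw[key] == pytest.approx(d1.e_vdw[key], abs=1e-8)
            assert d2.e_ele[key] == pytest.approx(d1.e_ele[key], abs=1e-8)

    def test_missing_side_chain_flagged(self):
        st = parse_structure(make_synthetic_structure("AWA", "strand", seed=2), "A")
        decomp = residue_gas_energy(st, PARAMS)
        assert ("A", 2, "") in decomp.incomplete

    def test_table_roundtrip(self, dipeptide):
        decomp = residue_gas_energy(dipeptide, PARAMS)
        back = read_energy_table(write_energy_table(decomp))
        for key in decomp.e_int:
            assert back.e_int[key] == pytest.approx(decomp.e_int[key], abs=1e-6)


class TestRelaxClashes:
    def _pair_structure(self, d):
        res1 = Residue("A", 1, "", "GLY", [AtomRecord(1, "CA", "C", np.zeros(3))])
        res2 = Residue("A", 2, "", "GLY", [AtomRecord(2, "CA", "C", np.array([d, 0.0, 0.0]))])
        return ProteinStructure("pair", [res1, res2])

    def test_clash_free_unchanged(self):
        st = self._pair_structure(5.0)
        out = relax_clashes(st, PARAMS, max_steps=50)
        assert np.allclose(out.residues[0].atoms[0].position, st.residues[0].atoms[0].position)

    def test_clashing_atoms_move_apart(self):
        st = self._pair_structure(1.0)
        out = relax_clashes(st, PARAMS, max_steps=200, step=0.05)
        d = np.linalg.norm(
            out.residues[0].atoms[0].position - out.residues[1].atoms[0].position
        )
        assert d > 1.0

    def test_zero_step_is_identity(self):
        st = self._pair_structure(1.0)
        out = relax_clashes(st, PARAMS, step=0.0)
        assert out is st
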