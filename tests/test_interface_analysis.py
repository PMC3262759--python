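"""Contact search, NRBC, Shrake-Rupley SASA and BSA."""

import numpy as np
import pytest

from tfdnabench.interface_analysis import (
    InterfaceError,
    compute_bsa,
    compute_nrbc,
    compute_sasa,
    find_contacts,
    identify_binding_units,
    residue_contact_profile,
    select_representative_unit,
    BindingUnit,
)
from tfdnabench.structure_io import (
    Atom,
    AtomClass,
    Chain,
    MolType,
    Residue,
    classify_atom,
)
from tfdnabench.synthetic_fixtures import (
    audit_contact_count,
    build_bdna,
    build_peptide,
    place_with_contacts,
    transform_chain,
)


def _atom(name, res_name, moltype, xyz):
    return Atom(name=name, element=name[0], coords=np.asarray(xyz, float),
                atom_class=classify_atom(res_name, name, moltype))


def _protein_res(chain, seq, res_name, atoms):
    r = Residue(chain_id=chain, seq_id=seq, res_name=res_name,
                moltype=MolType.AMINO_ACID)
    r.atoms = [_atom(n, res_name, MolType.AMINO_ACID, x) for n, x in atoms]
    return r


def _dna_res(chain, seq, res_name, atoms):
    r = Residue(chain_id=chain, seq_id=seq, res_name=res_name,
                moltype=MolType.NUCLEOTIDE)
    r.atoms = [_atom(n, res_name, MolType.NUCLEOTIDE, x) for n, x in atoms]
    return r


class TestFindContacts:
    def test_far_apart_no_contacts(self, duplex16, helix18):
        far = transform_chain(helix18, np.eye(3), np.array([200.0, 0, 0]))
        assert find_contacts([far], duplex16.dna_chains) == []

    def test_engineered_arginine_base_contact(self):
        # ARG NH1 placed 4.4 A from a base N7: one record, both flags set
        prot = Chain(chain_id="A")
        prot.residues.append(_protein_res("A", 1, "ARG", [
            ("N", (0, 0, 20)), ("CA", (1.5, 0, 20)), ("C", (2.2, 1.3, 20)),
            ("O", (1.8, 2.4, 20)), ("CB", (2.0, -1.2, 18)),
            ("NH1", (0, 0, 4.4)),
        ]))
        dna = Chain(chain_id="B")
        dna.residues.append(_dna_res("B", 1, "DG", [
            ("C1'", (3.0, 3.0, 0)), ("P", (6.0, 3.0, 0)), ("N7", (0, 0, 0)),
        ]))
        records = find_contacts([prot], [dna])
        assert len(records) == 1
        rec = records[0]
        assert rec.via_sidechain and rec.to_base and rec.sidechain_to_base
        assert rec.min_distance == pytest.approx(4.4)

    def test_backbone_only_contact_not_nrbc_qualifying(self):
        # backbone N near a base: contact exists but never counts for NRBC
        prot = Chain(chain_id="A")
        prot.residues.append(_protein_res("A", 1, "SER", [
            ("N", (0, 0, 4.0)), ("CA", (1.5, 0, 6.0)), ("OG", (0, 3.0, 12.0)),
        ]))
        dna = Chain(chain_id="B")
        dna.residues.append(_dna_res("B", 1, "DA", [("N7", (0, 0, 0))]))
        rec = find_contacts([prot], [dna])[0]
        assert rec.to_base and not rec.sidechain_to_base
        unit = BindingUnit("t", ["A"], ["B"], "monomer", [rec],
                           [prot], [dna])
        assert compute_nrbc(unit) == 0

    def test_grid_equals_brute_force(self):
        # randomized point clouds; KD-tree search must equal all-pairs
        rng = np.random.default_rng(42)
        for _ in range(50):
            prot = Chain(chain_id="A")
            for i in range(rng.integers(2, 6)):
                atoms = [("CA", rng.uniform(-10, 10, 3)),
                         ("CB", rng.uniform(-10, 10, 3))]
                prot.residues.append(_protein_res("A", i + 1, "ALA", atoms))
            dna = Chain(chain_id="B")
            for j in range(rng.integers(2, 6)):
                atoms = [("P", rng.uniform(-10, 10, 3)),
                         ("N1", rng.uniform(-10, 10, 3))]
                dna.residues.append(_dna_res("B", j + 1, "DC", atoms))
            got = {(c.residue_ref, c.nucleotide_ref,
                    round(c.min_distance, 6), c.via_sidechain, c.to_base)
                   for c in find_contacts([prot], [dna])}
            expected = set()
            for r in prot.residues:
                for n in dna.residues:
                    dists = [(np.linalg.norm(a.coords - b.coords), a, b)
                             for a in r.atoms for b in n.atoms]
                    hits = [(d, a, b) for d, a, b in dists if d <= 4.5]
                    if hits:
                        expected.add((
                            (r.chain_id, r.seq_id, r.res_name),
                            (n.chain_id, n.seq_id, n.res_name),
                            round(min(d for d, _, _ in hits), 6),
                            any(a.atom_class is AtomClass.PROTEIN_SIDECHAIN
                                for _, a, _ in hits),
                            any(b.atom_class is AtomClass.NUCLEOTIDE_BASE
                                for _, _, b in hits)))
            assert got == expected

    def test_requires_both_molecule_types(self, duplex16):
        with pytest.raises(InterfaceError):
            find_contacts([], duplex16.dna_chains)


class TestNrbc:
    def test_polyglycine_touching_dna_scores_zero(self, duplex16):
        gly = build_peptide("GGGGGGGGGG", "helix", chain_id="A")
        # park it right against the duplex: backbone contacts are plentiful
        # but there are no sidechain atoms at all
        coords = np.concatenate([c.coords() for c in duplex16.dna_chains])
        center = coords.mean(axis=0)
        gly_center = np.array([a.coords for a in gly.atoms()]).mean(axis=0)
        near = transform_chain(gly, np.eye(3),
                               center + np.array([11.0, 0, 0]) - gly_center)
        contacts = find_contacts([near], duplex16.dna_chains)
        unit = BindingUnit("t", ["A"], ["C", "D"], "monomer", contacts,
                           [near], duplex16.dna_chains)
        assert compute_nrbc(unit) == 0

    def test_engineered_count_is_recovered(self, complex_k5):
        units = identify_binding_units(complex_k5)
        assert len(units) == 1
        assert compute_nrbc(units[0]) == 5
        # audit independently with the brute-force counter
        assert audit_contact_count(complex_k5.protein_chains[0],
                                   complex_k5.dna_chains) == 5

    def test_monotone_in_cutoff(self, complex_k5):
        chains = complex_k5.protein_chains
        dna = complex_k5.dna_chains
        counts = []
        for cutoff in (3.5, 4.0, 4.5, 5.0, 5.5):
            contacts = find_contacts(chains, dna, cutoff=cutoff)
            unit = BindingUnit("t", ["A"], ["C", "D"], "monomer", contacts,
                               chains, dna)
            counts.append(compute_nrbc(unit, cutoff=cutoff))
        assert counts == sorted(counts)

    def test_nrbc_bounded_by_contacting_residues(self, homodimer_complex):
        unit = identify_binding_units(homodimer_complex)[0]
        n_res = len({c.residue_key for c in unit.contacts})
        assert compute_nrbc(unit) <= n_res <= len(unit.contacts)


class TestBindingUnits:
    def test_weakly_contacting_chain_excluded(self, duplex16):
        comp = place_with_contacts(
            build_peptide("NQSDNQSDNQSDNQSDNQ", "helix", chain_id="A"),
            duplex16, k=5, seed=2)
        # chain E far away: 0 contacts, must not join the unit
        far = build_peptide("NQSDNQSD", "helix", chain_id="E")
        far = transform_chain(far, np.eye(3), np.array([300.0, 0, 0]))
        comp.chains.insert(1, far)
        units = identify_binding_units(comp)
        assert len(units) == 1
        assert units[0].tf_chain_ids == ["A"]

    def test_identical_chains_make_homodimer(self, homodimer_complex):
        unit = identify_binding_units(homodimer_complex)[0]
        assert unit.oligo_state == "homodimer"
        assert compute_nrbc(unit) == 12


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        a = Atom(name="C", element="C", coords=[0, 0, 0])
        area = compute_sasa([a])[0]
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.01

    def test_separated_atoms_are_additive(self):
        a = Atom(name="C", element="C", coords=[0, 0, 0])
        b = Atom(name="C", element="C", coords=[70, 0, 0])
        single = compute_sasa([a]).sum()
        assert compute_sasa([a, b]).sum() == pytest.approx(2 * single)

    def test_coincident_atoms_count_once(self):
        a = Atom(name="C", element="C", coords=[0, 0, 0])
        b = Atom(name="C", element="C", coords=[0, 0, 0])
        single = compute_sasa([a]).sum()
        assert compute_sasa([a, b]).sum() == pytest.approx(single)

    def test_convergence_with_point_count(self, helix18):
        atoms = [a for a in helix18.atoms()]
        lo = compute_sasa(atoms, n_sphere_points=960).sum()
        hi = compute_sasa(atoms, n_sphere_points=1920).sum()
        assert abs(hi - lo) / hi < 0.005

    def test_cross_check_against_independent_implementation(self, helix18):
        """Dual-route check against biotite's Shrake-Rupley."""
        import biotite.structure as struc
        atoms = list(helix18.atoms())
        arr = struc.AtomArray(len(atoms))
        from tfdnabench.interface_analysis import atom_radius
        for i, a in enumerate(atoms):
            arr.coord[i] = a.coords
            arr.element[i] = a.element
            arr.atom_name[i] = a.name
            arr.res_id[i] = 1
            arr.res_name[i] = "ALA"
            arr.chain_id[i] = "A"
        radii = np.array([atom_radius(a.element) for a in atoms])
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                            vdw_radii=radii).sum()
        ours = compute_sasa(atoms, n_sphere_points=960).sum()
        assert abs(ours - theirs) / theirs < 0.02


class TestBsa:
    def test_no_burial_when_separated(self, duplex16):
        pep = build_peptide("NQSD", "helix", chain_id="A")
        far = transform_chain(pep, np.eye(3), np.array([150.0, 0, 0]))
        unit = BindingUnit("t", ["A"], ["C", "D"], "monomer", [],
                           [far], duplex16.dna_chains)
        metrics = compute_bsa(unit, n_sphere_points=240)
        assert metrics.bsa == pytest.approx(0.0, abs=0.1)
        assert metrics.bsa == pytest.approx(
            0.5 * (metrics.asa_tf + metrics.asa_dna - metrics.asa_complex))

    def test_positive_burial_on_complex(self, complex_k5):
        unit = identify_binding_units(complex_k5)[0]
        metrics = compute_bsa(unit, n_sphere_points=240)
        assert metrics.bsa > 100.0

    def test_formula_is_symmetric_in_components(self, complex_k5):
        # swapping the roles of the two components leaves BSA unchanged
        unit = identify_binding_units(complex_k5)[0]
        tf, dna = unit.tf_atoms(), unit.dna_atoms()
        asa_1 = compute_sasa(tf, n_sphere_points=240).sum()
        asa_2 = compute_sasa(dna, n_sphere_points=240).sum()
        asa_12 = compute_sasa(tf + dna, n_sphere_points=240).sum()
        asa_21 = compute_sasa(dna + tf, n_sphere_points=240).sum()
        assert 0.5 * (asa_1 + asa_2 - asa_12) == pytest.approx(
            0.5 * (asa_2 + asa_1 - asa_21), abs=1e-6)


class TestContactProfile:
    def test_all_base_contacts_give_100_percent(self, complex_k5):
        unit = identify_binding_units(complex_k5)[0]
        base_only = [c for c in unit.contacts if c.sidechain_to_base]
        profile = residue_contact_profile([
            BindingUnit("t", ["A"], ["C", "D"], "monomer", base_only,
                        unit.tf_chains, unit.dna_chains)])
        for aa in profile.n_base:
            assert profile.pct_base(aa) == 100.0

    def test_mixed_serine_is_50_percent(self):
        # residue 1: OG 4.0 A from base N7 (base-contacting)
        # residue 2: OG 4.0 A from backbone P only (backbone-only)
        dna = Chain(chain_id="B")
        dna.residues.append(_dna_res("B", 1, "DA",
                                     [("N7", (0, 0, 0)), ("P", (9, 0, 0))]))
        prot = Chain(chain_id="A")
        prot.residues.append(_protein_res("A", 1, "SER", [
            ("OG", (0, 0, 4.0)), ("CA", (0, 0, 30.0)), ("N", (1, 0, 30.0)),
        ]))
        prot.residues.append(_protein_res("A", 2, "SER", [
            ("OG", (9, 0, 4.0)), ("CA", (9, 0, 30.0)), ("N", (10, 0, 30.0)),
        ]))
        recs = find_contacts([prot], [dna])
        unit = BindingUnit("t", ["A"], ["B"], "monomer", recs, [], [])
        profile = residue_contact_profile([unit])
        assert profile.pct_base("S") == pytest.approx(50.0)

    def test_glycine_never_in_profile(self, homodimer_complex):
        unit = identify_binding_units(homodimer_complex)[0]
        profile = residue_contact_profile([unit])
        assert "G" not in profile.n_base
        assert "G" not in profile.n_backbone_only


class TestRepresentativeSelection:
    def _unit_with_contacts(self, complex_k5, n):
        unit = identify_binding_units(complex_k5)[0]
        qualifying = [c for c in unit.contacts if c.sidechain_to_base]
        return BindingUnit("t", ["A"], ["C", "D"], "monomer",
                           qualifying[:n], unit.tf_chains, unit.dna_chains)

    def test_highest_nrbc_wins(self, complex_k5):
        strong = self._unit_with_contacts(complex_k5, 5)
        weak = self._unit_with_contacts(complex_k5, 2)
        chosen = select_representative_unit([weak, strong],
                                            n_sphere_points=120)
        assert compute_nrbc(chosen) == compute_nrbc(strong)

    def test_single_unit_short_circuit(self, complex_k5):
        unit = identify_binding_units(complex_k5)[0]
        assert select_representative_unit([unit]) is unit

    def test_empty_list_raises(self):
        with pytest.raises(InterfaceError):
            select_representative_unit([])
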