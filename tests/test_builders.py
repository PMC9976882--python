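"""B-DNA geometry, data protocols, scaffolds and system assembly."""

import numpy as np
import pytest

from dnabind.builders import (
    assemble_unbound,
    build_bdna,
    competitive_system,
    place_dummy_sites,
    positional_freeze,
    protocol1_data,
    protocol2_data,
    scaffold_restraints,
)
from dnabind.fixtures import binding_mode_data, clamp_fixture
from dnabind.model import DuplexSpec
from dnabind.restraints import total_restraint_energy
from scipy.spatial.distance import cdist


class TestBuildBdna:
    def test_rise_sets_end_to_end_length(self):
        dna = build_bdna(DuplexSpec("ATGCATGCAT"))  # 10 bp
        base = dna.site_indices(chains=["D"], name="BASE")
        z = dna.coords[base][:, 2]
        assert z.max() - z.min() == pytest.approx(9 * 3.38)

    def test_one_purine_n1_per_base_pair(self):
        spec = DuplexSpec("GCGATCGC")
        dna = build_bdna(spec)
        purines = [
            s for s in dna.sites
            if s.name == "N1" and s.residue_name[-1] in "AG"
        ]
        assert len(purines) == spec.n_bp

    def test_helical_periodicity_ten_bp(self):
        dna = build_bdna(DuplexSpec("ACGTACGTACGTACG"))  # 15 bp
        base = dna.site_indices(chains=["D"], name="BASE")
        xy1 = dna.coords[base[0]][:2]
        xy11 = dna.coords[base[10]][:2]  # 10 * 36 deg = full turn
        az1 = np.arctan2(xy1[1], xy1[0])
        az11 = np.arctan2(xy11[1], xy11[0])
        assert az1 == pytest.approx(az11, abs=1e-9)

    def test_deterministic_and_constant_p_spacing(self):
        dna1 = build_bdna(DuplexSpec("GCGATCGC"))
        dna2 = build_bdna(DuplexSpec("GCGATCGC"))
        np.testing.assert_array_equal(dna1.coords, dna2.coords)
        p = dna1.site_indices(chains=["D"], name="P")
        d = np.linalg.norm(np.diff(dna1.coords[p], axis=0), axis=1)
        assert np.allclose(d, d[0])

    def test_paired_n1_within_base_pair_window(self):
        dna = build_bdna(DuplexSpec("ACGTAC"))
        n = 6
        for i in range(1, n + 1):
            a = dna.coords[dna.index_of("D", i, "N1")]
            b = dna.coords[dna.index_of("E", n - i + 1, "N1")]
            assert 2.5 < np.linalg.norm(a - b) <= 3.2


class TestDummySites:
    def test_palindrome_has_one_dummy_per_pair(self):
        dna = place_dummy_sites(build_bdna(DuplexSpec("GCGATCGC")))
        dummies = [s for s in dna.sites if s.name == "DUMMY"]
        assert len(dummies) == 8

    def test_polyA_dummies_all_on_strand_one(self):
        dna = place_dummy_sites(build_bdna(DuplexSpec("AAAAAA")))
        dummies = [s for s in dna.sites if s.name == "DUMMY"]
        assert len(dummies) == 6
        assert {s.chain for s in dummies} == {"D"}

    def test_dummy_positions_coincide_with_parent_n1(self):
        dna = place_dummy_sites(build_bdna(DuplexSpec("GCGATCGC")))
        for d, p in dna.dummy_parent.items():
            np.testing.assert_array_equal(dna.coords[d], dna.coords[p])
            assert dna.sites[d].mass == 0.0
            assert dna.sites[d].charge == 0.0


class TestProtocol1:
    def test_counting(self, clamp):
        col = protocol1_data(
            clamp.protein, clamp.binding_residues[:4], clamp.dna,
            active_fraction=0.5,
        )
        assert len(col.groups) == 4
        assert all(len(g.restraints) == 8 for g in col.groups)
        assert all(g.n_active == 1 for g in col.groups)
        assert col.n_active_groups == 2
        assert col.n_restraints() == 4 * 8

    def test_infinite_prune_radius_no_exclusions(self, clamp):
        col = protocol1_data(
            clamp.protein, clamp.binding_residues, clamp.dna,
            prune_radius=np.inf,
        )
        assert col.exclusions == []

    def test_small_prune_radius_excludes_shared_dummies(self, clamp):
        col = protocol1_data(
            clamp.protein, clamp.binding_residues, clamp.dna,
            prune_radius=4.0,
        )
        assert col.exclusions
        # every exclusion ties the same dummy index in two different groups
        for (gi, ri), (gj, rj) in col.exclusions:
            assert gi != gj
            assert ri == rj

    def test_empty_binding_residues_rejected(self, clamp):
        with pytest.raises(ValueError, match="non-empty"):
            protocol1_data(clamp.protein, [], clamp.dna)


class TestProtocol2:
    def test_counting_six_residues(self, clamp):
        col = protocol2_data(clamp.protein, clamp.binding_residues, clamp.dna)
        n_p = len([s for s in clamp.dna.sites if s.name == "P"])
        assert n_p == 16
        assert len(col.groups) == 6
        assert col.n_restraints() == 6 * 16

    def test_glycine_falls_back_to_ca_with_warning(self, clamp):
        with pytest.warns(UserWarning, match="no CB"):
            col = protocol2_data(clamp.protein, [("A", 1)], clamp.dna)
        assert col.groups[0].restraints[0].site_a == ("A", 1, "CA")

    def test_native_pairs_are_subset_of_candidates(self, clamp):
        """Candidate list covers every actual interface pairing of the
        bound reference whose residue is in the binding domain."""
        col = protocol2_data(clamp.protein, clamp.binding_residues, clamp.dna)
        candidates = {
            (r.site_a, r.site_b) for g in col.groups for r in g.restraints
        }
        ref = clamp.reference
        for chain, resid in clamp.binding_residues:
            a = ref.coords[ref.index_of(chain, resid, "CB")]
            for s in ref.sites:
                if s.name == "P":
                    d = np.linalg.norm(a - ref.coords[ref.index_of(*s.key())])
                    if d <= 8.0:  # a native-contact-range pairing
                        assert ((chain, resid, "CB"), s.key()) in candidates

    def test_candidates_invariant_under_strand_swap(self):
        """For a palindromic duplex the Cbeta-P candidate set is symmetric
        under relabeling the two strands."""
        fx = clamp_fixture("GCGATCGC")
        col = protocol2_data(fx.protein, fx.binding_residues, fx.dna)
        pairs = {
            (r.site_a, r.site_b[1:]) for g in col.groups for r in g.restraints
        }
        swapped = {
            (a, b) for a, b in pairs
        }  # roles are (resid, name); strand swap permutes chain only
        assert pairs == swapped


class TestScaffold:
    def test_one_restraint_per_base_pair(self, clamp):
        cols = scaffold_restraints(clamp.protein, clamp.dna)
        dna_cols = [c for c in cols if any(
            r.site_a[2] == "N1" for g in c.groups for r in g.restraints
        )]
        assert len(dna_cols) == 1
        assert dna_cols[0].n_restraints() == 8

    def test_bound_conformation_has_zero_scaffold_energy(self, clamp):
        cols = scaffold_restraints(clamp.protein, clamp.dna)
        e, _ = total_restraint_energy(cols, clamp.reference, replica_scale=1.0)
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_distorted_protein_strains_scaffold(self, clamp):
        cols = scaffold_restraints(clamp.protein, clamp.dna)
        stretched = clamp.reference.copy()
        pidx = stretched.molecule_site_indices("protein")
        # pull the arc apart: scale protein coordinates radially
        center = stretched.coords[pidx].mean(axis=0)
        stretched.coords[pidx] = (stretched.coords[pidx] - center) * 1.5 + center
        e, _ = total_restraint_energy(cols, stretched, replica_scale=1.0)
        assert e > 0.0


class TestAssembleUnbound:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_minimum_separation_respected(self, clamp, seed):
        system = assemble_unbound(clamp.protein, clamp.dna, 30.0, seed)
        ip = system.molecule_site_indices("protein")
        idn = system.molecule_site_indices("dna")
        assert cdist(system.coords[ip], system.coords[idn]).min() >= 30.0

    def test_same_seed_identical_placement(self, clamp):
        a = assemble_unbound(clamp.protein, clamp.dna, 30.0, seed=5)
        b = assemble_unbound(clamp.protein, clamp.dna, 30.0, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_internal_geometry_preserved(self, clamp):
        from dnabind.analysis import kabsch_rmsd

        system = assemble_unbound(clamp.protein, clamp.dna, 30.0, seed=2)
        ip = system.molecule_site_indices("protein")
        assert kabsch_rmsd(system.coords[ip], clamp.protein.coords) < 1e-8
        idn = system.molecule_site_indices("dna")
        np.testing.assert_allclose(system.coords[idn], clamp.dna.coords)


class TestCompetitiveSystem:
    def _build(self, seed=0):
        fx = clamp_fixture()
        data = binding_mode_data(fx)
        return fx, competitive_system(
            fx.protein,
            DuplexSpec("GCGATCGC", label="duplexA"),
            DuplexSpec("GCGATCGC", label="duplexB"),
            data,
            seed=seed,
        )

    def test_symmetric_under_duplex_swap(self):
        """Identical duplexes sit as exact two-fold images: swapping the
        labels maps the assembly onto itself."""
        fx, (system, cols) = self._build()
        ia = system.molecule_site_indices("duplexA")
        ib = system.molecule_site_indices("duplexB")
        c2 = system.coords[ib] * np.array([-1.0, 1.0, -1.0])
        np.testing.assert_allclose(c2, system.coords[ia], atol=1e-9)

    def test_or_selection_shape(self):
        fx, (system, cols) = self._build()
        data = [c for c in cols if c.label == "data"][0]
        assert len(data.groups) == 2
        assert data.n_active_groups == 1
        assert len(data.groups[0].restraints) == len(data.groups[1].restraints)

    def test_protein_cannot_touch_both_duplexes(self):
        """With the duplexes 60 A apart, no single protein placement puts
        binding sites within data range (r4 = 8 A) of both."""
        fx, (system, cols) = self._build()
        ia = system.molecule_site_indices("duplexA")
        ib = system.molecule_site_indices("duplexB")
        gap = cdist(system.coords[ia], system.coords[ib]).min()
        protein_extent = np.ptp(fx.protein.coords, axis=0).max()
        assert gap > protein_extent + 2 * 8.0

    def test_missing_role_raises(self):
        fx = clamp_fixture()
        bad = [((("A", 4, "CA"))[0:3], (0, 99, "N1"))]
        with pytest.raises(KeyError):
            competitive_system(
                fx.protein,
                DuplexSpec("GCGATCGC", label="a"),
                DuplexSpec("GCGATCGC", label="b"),
                [(("A", 4, "CA"), (0, 99, "N1"))],
            )

    def test_freeze_adds_positional_collections(self):
        fx = clamp_fixture()
        system, cols = competitive_system(
            fx.protein,
            DuplexSpec("GCGATCGC", label="a"),
            DuplexSpec("GCGATCGC", label="b"),
            binding_mode_data(fx),
            freeze="apo",
        )
        anchored = [
            c for c in cols
            if any(r.site_b is None for g in c.groups for r in g.restraints)
        ]
        assert len(anchored) == 2
        e, _ = total_restraint_energy(anchored, system, replica_scale=1.0)
        assert e == pytest.approx(0.0, abs=1e-12)  # built coords satisfy them


class TestPositionalFreeze:
    def test_drift_beyond_width_costs_energy(self, clamp):
        col = positional_freeze(clamp.reference, "dna", width=1.0)
        e0, _ = total_restraint_energy([col], clamp.reference)
        assert e0 == 0.0
        moved = clamp.reference.coords.copy()
        idx = clamp.reference.molecule_site_indices("dna")
        moved[idx] += np.array([3.0, 0.0, 0.0])
        e1, _ = total_restraint_energy([col], clamp.reference, coords=moved)
        assert e1 > 0.0
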