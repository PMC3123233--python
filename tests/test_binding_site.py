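"""Contact predicate, ligand clustering, cluster selection and voting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pocketvote import (
    ContactParams, apply_voting, atoms_in_contact, centroid_ligand,
    cluster_ligands, ligand_contact, parse_pdb, predict,
    select_binding_cluster, tally_votes,
)
from pocketvote.binding_site import ResidueVote, write_fn_prediction
from pocketvote.errors import ClusteringError, InputError
from pocketvote.fixtures import make_toy_model
from pocketvote.structure_io import Atom, Ligand, Residue, StructureModel
from pocketvote.template_pipeline import TemplateEntry
from conftest import load_templates


def atom(x, y=0.0, z=0.0, element="C", name=None, hetero=True, serial=1):
    return Atom(serial, name or element, element, [x, y, z], is_hetero=hetero)


def single(x, y=0.0, z=0.0, element="ZN", het="ZN", iid=None):
    return Ligand(het, [atom(x, y, z, element)], instance_id=iid or f"{het}@{x}")


class TestAtomContact:
    # packaged radii: r(C) = 1.70, so the sum-mode C–C threshold is 3.90 Å
    def test_boundary_is_inclusive(self):
        p = ContactParams()
        assert atoms_in_contact(atom(0.0), atom(3.90), p)
        assert not atoms_in_contact(atom(0.0), atom(3.91), p)

    def test_single_radius_mode_uses_larger_radius(self):
        p = ContactParams(radius_mode="single_radius")
        # max(r) + margin = 1.70 + 0.5 = 2.20
        assert atoms_in_contact(atom(0.0), atom(2.20), p)
        assert not atoms_in_contact(atom(0.0), atom(2.21), p)

    def test_coincident_atoms_touch_in_both_modes(self):
        for mode in ("sum_of_radii", "single_radius"):
            assert atoms_in_contact(atom(0.0), atom(0.0),
                                    ContactParams(radius_mode=mode))

    def test_symmetric(self):
        a, b = atom(0.0, element="ZN"), atom(3.0, element="N")
        p = ContactParams()
        assert atoms_in_contact(a, b, p) == atoms_in_contact(b, a, p)

    def test_negative_margin_rejected(self):
        with pytest.raises(InputError):
            ContactParams(margin=-0.1)


class TestLigandContact:
    def test_close_and_far_single_atoms(self):
        p = ContactParams()
        assert ligand_contact(single(0.0), single(1.0, iid="b"), p)
        assert not ligand_contact(single(0.0), single(50.0, iid="b"), p)

    def test_existential_over_atoms(self):
        # a multi-atom ligand counts as contacting if ANY atom pair touches
        gdp = Ligand("GDP", [atom(0.0), atom(30.0, serial=2)], instance_id="gdp")
        po4 = Ligand("PO4", [atom(33.0, element="P")], instance_id="po4")
        assert ligand_contact(gdp, po4, ContactParams())  # via the 30 Å atom

    def test_hydrogens_ignored(self):
        l1 = Ligand("GDP", [atom(0.0)], instance_id="a")
        h_only_near = Ligand(
            "GDP", [Atom(1, "H", "H", [2.0, 0, 0], is_hetero=True, is_hydrogen=True),
                    atom(40.0, serial=2)],
            instance_id="b")
        assert not ligand_contact(l1, h_only_near, ContactParams())


def bfs_components(ligands, params):
    """Independent oracle: breadth-first search over the contact matrix."""
    n = len(ligands)
    adj = [[ligand_contact(ligands[i], ligands[j], params)
            for j in range(n)] for i in range(n)]
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp, queue = set(), [s]
        while queue:
            u = queue.pop()
            if u in comp:
                continue
            comp.add(u)
            queue.extend(v for v in range(n) if adj[u][v] and v not in comp)
        seen |= comp
        comps.append(frozenset(ligands[i].instance_id for i in comp))
    return set(comps)


class TestClustering:
    def test_contact_chain_is_transitive(self):
        # A-B touch, B-C touch, A-C do not -> one continuous mass
        a, b, c = single(0.0, iid="a"), single(3.0, iid="b"), single(6.0, iid="c")
        clusters = cluster_ligands([a, b, c])
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_two_separate_masses(self):
        group1 = [single(x, iid=f"g1-{x}") for x in (0.0, 3.0, 6.0)]
        group2 = [single(x, y=100.0, iid=f"g2-{x}") for x in (0.0, 3.0)]
        clusters = cluster_ligands(group1 + group2)
        assert sorted(c.size for c in clusters) == [2, 3]
        assert clusters[0].size == 3  # ids ordered by decreasing size

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ClusteringError):
            cluster_ligands([])

    @given(st.integers(0, 10_000))
    def test_matches_bfs_oracle_on_random_pools(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 15))
        params = ContactParams()
        ligands = [single(*rng.uniform(0, 12, size=3), iid=f"L{i}")
                   for i in range(n)]
        clusters = cluster_ligands(ligands, params)
        got = {frozenset(c.member_ids()) for c in clusters}
        assert got == bfs_components(ligands, params)
        assert sum(c.size for c in clusters) == n


class TestClusterSelection:
    def test_strict_maximum_wins(self):
        sizes = {"a": 5, "b": 3, "c": 1}
        pools = []
        for k, (name, sz) in enumerate(sizes.items()):
            pools += [single(3.0 * i, y=50.0 * k, iid=f"{name}{i}") for i in range(sz)]
        clusters = cluster_ligands(pools)
        assert select_binding_cluster(clusters).size == 5

    def test_single_cluster_returns_itself(self):
        clusters = cluster_ligands([single(0.0, iid="only")])
        assert select_binding_cluster(clusters) is clusters[0]

    def test_size_tie_broken_by_residue_contact_count(self):
        # two 2-ligand clusters; the model hugs the second one
        model = make_toy_model(6, geometry="extended", seed=0)
        c1 = [single(0.0, y=300.0, iid=f"far{i}") for i in (0.0, 3.0)]
        near_ca = model.residues[2].ca().coords
        c2 = [single(near_ca[0], near_ca[1] + 3.0, near_ca[2], iid=f"near{i}")
              for i in (0.0, 3.0)]
        c2[1].atoms[0].coords = c2[0].atoms[0].coords + np.array([0, 1.0, 0])
        clusters = cluster_ligands(c1 + c2)
        chosen = select_binding_cluster(clusters, model, ContactParams())
        assert set(chosen.member_ids()) == {"near0.0", "near3.0"}

    def test_final_tie_broken_by_smallest_instance_id(self):
        clusters = cluster_ligands([single(0.0, iid="bbb"), single(0.0, y=99.0, iid="aaa")])
        assert select_binding_cluster(clusters).member_ids() == ["aaa"]


class TestCentroid:
    def test_single_member(self):
        clusters = cluster_ligands([single(0.0, iid="x")])
        assert centroid_ligand(clusters[0]).instance_id == "x"

    def test_middle_of_three_collinear(self):
        ligs = [single(x, iid=f"p{x}") for x in (0.0, 3.0, 6.0)]
        cluster = cluster_ligands(ligs)[0]
        assert centroid_ligand(cluster).instance_id == "p3.0"

    def test_matches_brute_force_distance_sum(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 8))
            ligs = [single(*rng.uniform(0, 6, size=3), iid=f"L{i}")
                    for i in range(n)]
            clusters = cluster_ligands(ligs)
            for cluster in clusters:
                centers = [m.center() for m in cluster.members]
                sums = [sum(np.linalg.norm(c - d) for d in centers) for c in centers]
                best = min(sums)
                expect = min(m.instance_id for m, s in zip(cluster.members, sums)
                             if abs(s - best) < 1e-9)
                assert centroid_ligand(cluster).instance_id == expect


class TestVoting:
    def _votes(self, tallies):
        return [
            ResidueVote(
                residue=Residue("A", i + 1, " ", "ALA", [atom(0, hetero=False)]),
                contacted={f"L{k}" for k in range(v)})
            for i, v in enumerate(tallies)
        ]

    def test_tally_uses_set_semantics_not_atom_counts(self):
        # three atoms of one residue all touch the same single-atom ligand;
        # a second residue sits far away
        r1 = Residue("A", 1, " ", "ALA", [
            atom(0.0, hetero=False), atom(1.0, hetero=False, serial=2),
            atom(2.0, hetero=False, serial=3)])
        r2 = Residue("A", 2, " ", "ALA", [atom(50.0, hetero=False, serial=4)])
        model = StructureModel("t", [r1, r2])
        lig = single(1.0, y=3.0, iid="only")
        votes = tally_votes(model, cluster_ligands([lig])[0])
        assert len(votes) == 1 and votes[0].votes == 1
        assert votes[0].residue is r1

    def test_distant_residues_omitted(self):
        model = make_toy_model(5, geometry="extended", seed=0)
        lig = single(0.0, y=500.0, iid="far")
        assert tally_votes(model, cluster_ligands([lig])[0]) == []

    @pytest.mark.parametrize("votes,size,included", [
        (5, 13, True),    # 38.46% — in
        (7, 13, True),    # 53.85% — in
        (2, 13, False),   # 15.38% — out (fraction)
        (1, 13, False),   # 7.69% — out
        (8, 13, True),    # 61.54% — in
        (4, 13, True),    # 30.77% — in
        (3, 13, False),   # 23.08% — out (fraction)
        (3, 9, True),     # 33.33% — in
        (1, 2, False),    # 50% but fails the 2-ligand minimum
        (2, 8, True),     # exactly 25% — inclusive boundary
        (2, 9, False),    # just below 25%
    ])
    def test_inclusion_rule(self, votes, size, included):
        vote_list = self._votes([votes])
        kept = apply_voting(vote_list, cluster_size=size)
        assert (len(kept) == 1) == included

    def test_exact_quarter_boundary_is_float_safe(self):
        # 25% of 4·k ligands must stay inclusive for any k
        for k in (1, 3, 7, 25, 1001):
            kept = apply_voting(self._votes([k]), cluster_size=4 * k)
            assert len(kept) == (1 if k >= 2 else 0)

    def test_output_sorted_by_residue_identifier(self):
        votes = list(reversed(self._votes([5, 6, 7])))
        kept = apply_voting(votes, cluster_size=13)
        assert [r.seq_num for r in kept] == [1, 2, 3]

    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=15),
        st.integers(1, 6), st.integers(1, 6),
        st.sampled_from([0.0, 0.1, 0.25, 0.3, 0.5, 0.75]),
        st.sampled_from([0.05, 0.1, 0.25, 0.4]),
    )
    def test_raising_thresholds_never_adds_residues(
            self, tallies, min_lig, dlig, frac, dfrac):
        size = max(max(tallies), 1)
        tallies = [min(t, size) for t in tallies]
        votes = self._votes(tallies)
        loose = {r.seq_num for r in apply_voting(votes, size, min_lig, frac)}
        tight_l = {r.seq_num for r in apply_voting(votes, size, min_lig + dlig, frac)}
        tight_f = {r.seq_num for r in apply_voting(votes, size, min_lig,
                                                   min(frac + dfrac, 1.0))}
        assert tight_l <= loose and tight_f <= loose


class TestPredict:
    def test_planted_pocket_recovered_exactly(self, planted_bundle):
        model, _ = parse_pdb(planted_bundle.model_path)
        templates = load_templates(planted_bundle.template_paths)
        prediction, results = predict(model, templates)
        assert all(r.accepted for r in results)
        got = sorted(r.token() for r in prediction.predicted_residues)
        assert got == planted_bundle.ground_truth["predicted_residues"]
        assert prediction.cluster.size == len(templates)

    def test_all_templates_below_gate_yield_empty_prediction(self):
        model = make_toy_model(40, geometry="helix", seed=0)
        coil = make_toy_model(40, geometry="random_coil", seed=7)
        templates = [TemplateEntry(template_id="coil", structure=coil, ligands=[
            single(0.0, iid="zn")])]
        prediction, results = predict(model, templates)
        assert prediction.is_empty
        assert prediction.empty_reason == "no accepted superpositions"
        assert not results[0].accepted

    def test_no_ligands_yields_empty_prediction_with_reason(self):
        model = make_toy_model(20, seed=0)
        templates = [TemplateEntry(template_id="bare", structure=model, ligands=[])]
        prediction, _ = predict(model, templates)
        assert prediction.is_empty
        assert prediction.empty_reason == "no relevant ligands"

    def test_deterministic_fn_output(self, figure1_bundle, tmp_path):
        model, _ = parse_pdb(figure1_bundle.model_path)
        templates = load_templates(figure1_bundle.template_paths)
        files = []
        for name in ("a.fn", "b.fn"):
            prediction, _ = predict(model, templates)
            out = tmp_path / name
            write_fn_prediction(prediction, out)
            files.append(out.read_bytes())
        assert files[0] == files[1]
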