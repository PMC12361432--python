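"""Structural metrics vs exhaustive/closed-form oracles and planted ground truth."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from ccr9map.core_io import Ensemble, StructureModel
from ccr9map.structure import (
    AtomScoreTable,
    DEFAULT_TM_RANGES,
    activation_distance,
    aggregate_atom_scores,
    contact_map,
    disulfide_partners,
    ensemble_variability,
    hbond_network,
    rank_by_activation,
    select_mutagenesis_sites,
    superpose,
    tm_displacement,
)
from ccr9map.synthetic import ToyEnsembleSpec, generate_toy_ensemble


def model_from_rows(rows, model_id="m", roles=None):
    atoms = pd.DataFrame(rows, columns=list(StructureModel.ATOM_COLUMNS))
    return StructureModel(model_id, atoms, roles or {"A": "receptor"})


def random_rigid(rng):
    rot = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
    trans = rng.uniform(-50, 50, 3)
    return rot, trans


class TestSuperpose:
    def _ca_model(self, coords, model_id="m"):
        rows = [("A", i + 1, "GLY", "CA", "C", *xyz, 90.0) for i, xyz in enumerate(coords)]
        return model_from_rows(rows, model_id)

    def test_self_superposition_is_identity(self, rng):
        m = self._ca_model(rng.uniform(-10, 10, (8, 3)))
        rot, trans, rmsd = superpose(m, m)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(trans, 0.0, atol=1e-6)

    def test_known_rigid_transform_recovered(self, rng):
        coords = rng.uniform(-10, 10, (10, 3))
        ref = self._ca_model(coords, "ref")
        for _ in range(50):
            rot, trans = random_rigid(rng)
            mob = self._ca_model(coords @ rot.T + trans, "mob")
            r, t, rmsd = superpose(mob, ref)
            assert rmsd == pytest.approx(0.0, abs=1e-6)
            np.testing.assert_allclose(r @ rot, np.eye(3), atol=1e-6)

    def test_rmsd_matches_closed_form_on_three_atoms(self, rng):
        """After optimal superposition RMSD equals the Kabsch closed form."""
        for _ in range(200):
            a = rng.uniform(-5, 5, (3, 3))
            b = rng.uniform(-5, 5, (3, 3))
            _, _, rmsd = superpose(self._ca_model(b), self._ca_model(a))
            # closed form via SVD of the covariance (proper rotation enforced)
            ac, bc = a - a.mean(0), b - b.mean(0)
            u, s, vt = np.linalg.svd(bc.T @ ac)
            d = np.sign(np.linalg.det(u @ vt))
            e0 = (ac ** 2).sum() + (bc ** 2).sum()
            msd = max((e0 - 2 * (s[0] + s[1] + d * s[2])) / 3, 0.0)
            assert rmsd == pytest.approx(math.sqrt(msd), abs=1e-6)

    def test_two_atom_selection_rejected(self, rng):
        m = self._ca_model(rng.uniform(-5, 5, (8, 3)))
        with pytest.raises(ValueError, match=">= 3"):
            superpose(m, m, selection=[1, 2])


class TestEnsembleVariability:
    def test_duplicated_models_have_zero_rmsf(self, toy_ensemble):
        ens, _ = toy_ensemble
        dup = Ensemble([ens.models[0], ens.models[0]], "R", "C")
        out = ensemble_variability(dup)
        np.testing.assert_allclose(out["rmsf"], 0.0, atol=1e-9)

    def test_planted_jitter_recovered(self):
        sigma = 0.3
        ens, _ = generate_toy_ensemble(
            ToyEnsembleSpec(n_models=50, jitter_sd=sigma), seed=3)
        out = ensemble_variability(ens)
        expect = sigma * math.sqrt(3) * math.sqrt(49 / 50)
        assert out["rmsf"].mean() == pytest.approx(expect, rel=0.10)

    def test_constant_confidence_reported(self, toy_ensemble):
        ens, _ = toy_ensemble
        out = ensemble_variability(ens)
        np.testing.assert_allclose(out["mean_confidence"], 92.0)

    def test_single_model_rejected(self, toy_ensemble):
        ens, _ = toy_ensemble
        single = Ensemble([ens.models[0]], "R", "C")
        with pytest.raises(ValueError, match=">= 2"):
            ensemble_variability(single)


class TestActivationDistance:
    def test_planted_separations(self, toy_ensemble):
        ens, truth = toy_ensemble
        for model, d in zip(ens.models, truth["activation_distances"]):
            assert activation_distance(model) == pytest.approx(d, abs=1e-6)

    def test_matches_bruteforce_min_over_amide_atoms(self, rng):
        for _ in range(300):
            oh = rng.uniform(-10, 10, 3)
            nd2 = rng.uniform(-10, 10, 3)
            od1 = rng.uniform(-10, 10, 3)
            rows = [
                ("A", 126, "TYR", "OH", "O", *oh, 90.0),
                ("A", 271, "ASN", "ND2", "N", *nd2, 90.0),
                ("A", 271, "ASN", "OD1", "O", *od1, 90.0),
            ]
            m = model_from_rows(rows)
            expect = min(np.linalg.norm(nd2 - oh), np.linalg.norm(od1 - oh))
            assert activation_distance(m) == pytest.approx(expect, abs=1e-9)

    def test_missing_amide_atoms_named_in_error(self):
        m = model_from_rows([("A", 126, "TYR", "OH", "O", 0, 0, 0, 90.0)])
        with pytest.raises(KeyError, match="ND2"):
            activation_distance(m)

    def test_rigid_transform_invariance(self, toy_ensemble, rng):
        ens, _ = toy_ensemble
        model = ens.models[2]
        base = activation_distance(model)
        for _ in range(10):
            rot, trans = random_rigid(rng)
            assert activation_distance(model.transformed(rot, trans)) == pytest.approx(
                base, abs=1e-9)


class TestRanking:
    def test_planted_monotone_order(self, toy_ensemble):
        ens, truth = toy_ensemble
        ranked, best = rank_by_activation(ens)
        # planted distances increase with model index, so ranking reverses it
        assert [m.model_id for m in ranked] == [f"model_{i:02d}" for i in (5, 4, 3, 2, 1)]
        assert best.model_id == "model_05"

    def test_single_model_ensemble(self, toy_ensemble):
        ens, _ = toy_ensemble
        single = Ensemble([ens.models[0]], "R", "C")
        _, best = rank_by_activation(single)
        assert best.model_id == ens.models[0].model_id

    def test_ties_broken_by_model_id(self):
        ens, _ = generate_toy_ensemble(ToyEnsembleSpec(n_models=4, activation_distance=5.0),
                                       seed=1)
        ranked, _ = rank_by_activation(ens)
        assert [m.model_id for m in ranked] == sorted(m.model_id for m in ens.models)


class TestTmDisplacement:
    def _segment_and_frame(self):
        tm5 = DEFAULT_TM_RANGES[5]
        segment = list(range(tm5[0], tm5[1] + 1))
        frame = [r for lo, hi in DEFAULT_TM_RANGES.values()
                 for r in range(lo, hi + 1) if r not in set(segment)]
        return segment, frame

    def test_identical_structures_give_zero(self, toy_ensemble):
        ens, _ = toy_ensemble
        segment, frame = self._segment_and_frame()
        out = tm_displacement(ens.models[0], ens.models[0], segment, frame)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_planted_axial_slide_recovered(self):
        ens, truth = generate_toy_ensemble(ToyEnsembleSpec(tm5_shift=6.0), seed=2)
        segment, frame = self._segment_and_frame()
        outward, along, total = tm_displacement(ens.models[0], ens.reference_inactive,
                                                segment, frame)
        assert along == pytest.approx(6.0, abs=0.1)
        assert outward == pytest.approx(0.0, abs=0.1)

    def test_planted_radial_shift_recovered(self):
        ens, _ = generate_toy_ensemble(
            ToyEnsembleSpec(tm5_shift=0.0, tm5_shift_radial=4.0), seed=2)
        segment, frame = self._segment_and_frame()
        outward, along, total = tm_displacement(ens.models[0], ens.reference_inactive,
                                                segment, frame)
        assert outward == pytest.approx(4.0, abs=0.1)
        assert along == pytest.approx(0.0, abs=0.1)
        assert total == pytest.approx(4.0, abs=0.1)


class TestContacts:
    def _two_chain_model(self, rec_xyz, chem_xyz, rng=None):
        rows = [("R", i + 1, "LEU", "CB", "C", *xyz, 90.0) for i, xyz in enumerate(rec_xyz)]
        rows += [("C", i + 1, "SER", "OG", "O", *xyz, 90.0) for i, xyz in enumerate(chem_xyz)]
        m = model_from_rows(rows, roles={"R": "receptor", "C": "chemokine"})
        return Ensemble([m], "R", "C")

    def test_distant_chains_have_no_contacts(self, rng):
        ens = self._two_chain_model(rng.uniform(0, 5, (10, 3)),
                                    rng.uniform(100, 105, (10, 3)))
        assert contact_map(ens) == []

    def test_zero_cutoff_is_empty(self, toy_ensemble):
        ens, _ = toy_ensemble
        assert contact_map(ens, cutoff=0.0) == []

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(50):
            rec = rng.uniform(0, 12, (15, 3))
            chem = rng.uniform(0, 12, (12, 3))
            ens = self._two_chain_model(rec, chem)
            records = contact_map(ens, cutoff=4.5)
            got = {(r.receptor_residue, r.chemokine_residue): r.min_heavy_atom_distance
                   for r in records}
            d = cdist(rec, chem)
            expect = {(i + 1, j + 1): d[i, j] for i in range(15) for j in range(12)
                      if d[i, j] <= 4.5}
            assert set(got) == set(expect)
            for k in got:
                assert got[k] == pytest.approx(expect[k], abs=1e-9)

    def test_planted_contacts_recovered_with_full_fraction(self, toy_ensemble):
        ens, truth = toy_ensemble
        records = contact_map(ens, sidechain_only=True)
        strong = {r.receptor_residue for r in records if r.model_fraction == 1.0}
        assert set(truth["contact_residues"]) <= strong
        assert not (set(truth["weak_contact_residues"]) & strong)


class TestSiteSelection:
    def test_planted_sites_recovered(self, toy_ensemble):
        ens, truth = toy_ensemble
        contacts = contact_map(ens, sidechain_only=True)
        tm = {r for lo, hi in DEFAULT_TM_RANGES.values() for r in range(lo, hi + 1)}
        sites = select_mutagenesis_sites(contacts, k=5, restrict=tm)
        assert sorted(sites) == truth["contact_residues"]

    def test_k_zero_is_empty(self, toy_ensemble):
        ens, _ = toy_ensemble
        assert select_mutagenesis_sites(contact_map(ens), k=0) == []

    def test_ties_prefer_lower_residue_number(self):
        from ccr9map.structure import ContactRecord
        contacts = [
            ContactRecord(50, 10, 3.8, True, 1.0, 2.0),
            ContactRecord(40, 11, 3.8, True, 1.0, 2.0),
        ]
        assert select_mutagenesis_sites(contacts, k=1) == [40]

    def test_too_few_candidates_warn(self, toy_ensemble):
        ens, _ = toy_ensemble
        contacts = contact_map(ens, sidechain_only=True)
        with pytest.warns(UserWarning, match="candidate"):
            select_mutagenesis_sites(contacts, k=50)


class TestHbonds:
    def test_close_n_o_pair_detected(self):
        rows = [("A", 1, "LYS", "NZ", "N", 0, 0, 0, 90.0),
                ("B", 2, "SER", "O", "O", 2.9, 0, 0, 90.0)]
        m = model_from_rows(rows, roles={"A": "receptor", "B": "chemokine"})
        bonds = hbond_network(m, [("A", 1)])
        assert len(bonds) == 1
        assert bonds[0].donor == ("A", 1, "NZ")
        assert bonds[0].dha_angle is None
        assert not bonds[0].donor_backbone and bonds[0].acceptor_backbone

    def test_pair_beyond_cutoff_absent(self):
        rows = [("A", 1, "LYS", "NZ", "N", 0, 0, 0, 90.0),
                ("B", 2, "SER", "O", "O", 4.0, 0, 0, 90.0)]
        m = model_from_rows(rows, roles={"A": "receptor", "B": "chemokine"})
        assert hbond_network(m, [("A", 1)]) == []

    def test_angle_criterion_applied_when_hydrogens_exist(self):
        base = [("A", 1, "LYS", "NZ", "N", 0, 0, 0, 90.0),
                ("B", 2, "SER", "O", "O", 2.9, 0, 0, 90.0)]
        # hydrogen placed between donor and acceptor: angle ~180 -> kept
        good = base + [("A", 1, "LYS", "HZ1", "H", 1.0, 0, 0, 90.0)]
        m = model_from_rows(good, roles={"A": "receptor", "B": "chemokine"})
        assert len(hbond_network(m, [("A", 1)])) == 1
        # hydrogen pointing away: angle ~0 -> rejected
        bad = base + [("A", 1, "LYS", "HZ1", "H", -1.0, 0, 0, 90.0)]
        m = model_from_rows(bad, roles={"A": "receptor", "B": "chemokine"})
        assert hbond_network(m, [("A", 1)]) == []

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(100):
            n = 15
            rows = []
            for i in range(n):
                elem = "N" if i % 2 else "O"
                rows.append(("A", i + 1, "GLY", elem, elem, *rng.uniform(0, 8, 3), 90.0))
            m = model_from_rows(rows)
            focus = [("A", i + 1) for i in range(n)]
            got = {frozenset([b.donor, b.acceptor]) for b in hbond_network(m, focus)}
            coords = np.array([r[5:8] for r in rows])
            expect = set()
            for i in range(n):
                for j in range(i + 1, n):
                    if np.linalg.norm(coords[i] - coords[j]) <= 3.5:
                        expect.add(frozenset([("A", i + 1, rows[i][3]),
                                              ("A", j + 1, rows[j][3])]))
            assert got == expect

    def test_planted_network_count(self, toy_ensemble):
        ens, truth = toy_ensemble
        bonds = hbond_network(ens.models[0], [("R", 211)])
        planted = [b for b in bonds
                   if b.donor[:2] == ("R", 211) and not b.donor_backbone
                   and b.acceptor[0] == "C" and b.acceptor_backbone]
        assert len(planted) == len(truth["hbond_pairs"]) == 3
        assert sorted(b.acceptor[1] for b in planted) == sorted(
            p for _, p in truth["hbond_pairs"])


class TestDisulfides:
    def _cys_model(self, positions):
        rows = [("C", res, "CYS", "SG", "S", *xyz, 90.0) for res, xyz in positions.items()]
        return model_from_rows(rows, roles={"C": "receptor"})

    def test_single_bridge_detected(self):
        m = self._cys_model({7: (0, 0, 0), 35: (2.05, 0, 0)})
        assert disulfide_partners(m, "C") == [(7, 35)]

    def test_isolated_cysteine_unpaired(self):
        m = self._cys_model({7: (0, 0, 0), 35: (10, 0, 0)})
        assert disulfide_partners(m, "C") == []

    def test_greedy_matches_bruteforce_on_three_cys(self, rng):
        from itertools import permutations
        for _ in range(200):
            pos = {1: rng.uniform(0, 4, 3), 2: rng.uniform(0, 4, 3), 3: rng.uniform(0, 4, 3)}
            m = self._cys_model(pos)
            got = disulfide_partners(m, "C")
            # brute-force min-weight matching over <= 1 pair per Cys
            cand = [(np.linalg.norm(pos[i] - pos[j]), i, j)
                    for i in pos for j in pos if i < j
                    if np.linalg.norm(pos[i] - pos[j]) < 2.5]
            if not cand:
                assert got == []
            else:
                # with three cysteines at most one pair can form; greedy picks nearest
                best = min(cand)
                assert got == [(best[1], best[2])]

    def test_planted_bridge_in_toy_chemokine(self, toy_ensemble):
        ens, truth = toy_ensemble
        assert disulfide_partners(ens.models[0], "C") == [truth["disulfide"]]


class TestScoreAggregation:
    def _scored_model(self):
        rows = [("C", 1, "SER", a, a[0], i * 2.0, 0, 0, 90.0)
                for i, a in enumerate(["N", "CA", "C", "O", "OG"])]
        model = model_from_rows(rows, roles={"C": "receptor"})
        return model

    def test_zero_scores_aggregate_to_zero(self):
        model = self._scored_model()
        scores = AtomScoreTable(pd.DataFrame({
            "chain": "C", "seq_number": 1,
            "atom_name": ["N", "CA", "C", "O", "OG"], "score": 0.0}))
        out = aggregate_atom_scores(model, scores)
        assert out["backbone_score"].iloc[0] == 0.0
        assert out["sidechain_score"].iloc[0] == 0.0

    def test_unit_scores_count_atoms(self):
        model = self._scored_model()
        scores = AtomScoreTable(pd.DataFrame({
            "chain": "C", "seq_number": 1,
            "atom_name": ["N", "CA", "C", "O", "OG"], "score": 1.0}))
        out = aggregate_atom_scores(model, scores)
        assert out["backbone_score"].iloc[0] == pytest.approx(4.0)
        assert out["sidechain_score"].iloc[0] == pytest.approx(1.0)

    def test_two_model_average(self):
        model = self._scored_model()
        s1 = AtomScoreTable(pd.DataFrame({
            "chain": "C", "seq_number": 1,
            "atom_name": ["N", "CA", "C", "O", "OG"], "score": 1.0}))
        s2 = AtomScoreTable(pd.DataFrame({
            "chain": "C", "seq_number": 1,
            "atom_name": ["N", "CA", "C", "O", "OG"], "score": 3.0}))
        out = aggregate_atom_scores([model, model], [s1, s2])
        assert out["backbone_score"].iloc[0] == pytest.approx(8.0)
        assert out["sidechain_score"].iloc[0] == pytest.approx(2.0)

    def test_unresolvable_atom_listed(self):
        model = self._scored_model()
        scores = AtomScoreTable(pd.DataFrame({
            "chain": ["C"], "seq_number": [9], "atom_name": ["XX"], "score": [1.0]}))
        with pytest.raises(ValueError, match="9/XX"):
            aggregate_atom_scores(model, scores)
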