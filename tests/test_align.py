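"""Superposition, TM-score, heuristic alignment and label transfer."""

import numpy as np
import pytest

from conftest import random_rigid
from sprotann.align import (align_structures, classify_by_nearest, kabsch,
                            search_library, tm_d0, tm_score_fixed)
from sprotann.errors import ContractError
from sprotann.synthetic import (make_labeled_library, perturb_model,
                                random_sequence, standard_fold_specs,
                                make_fold)

FOUR_POINTS = np.array([
    [0.0, 0.0, 0.0],
    [3.0, 0.5, -0.2],
    [1.0, 4.0, 1.0],
    [-1.0, 1.0, 3.5],
])


@pytest.fixture(scope="module")
def bundle_pair():
    spec = standard_fold_specs()["two_helix_bundle"][1]
    seq = random_sequence(spec.total_length, np.random.default_rng(1))
    fold = make_fold(spec, seq, seed=3)
    pert = perturb_model(fold, 5.0, seed=7)
    return fold, pert


class TestKabsch:
    def test_exact_recovery_of_rigid_copy(self):
        rng = np.random.default_rng(3)
        rot, t = random_rigid(rng)
        moved = FOUR_POINTS @ rot.T + t
        sup = kabsch(FOUR_POINTS, moved)
        assert sup.rmsd < 1e-6
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_matches_transform_application(self):
        rng = np.random.default_rng(4)
        noisy = FOUR_POINTS + rng.normal(0, 0.7, FOUR_POINTS.shape)
        sup = kabsch(FOUR_POINTS, noisy)
        diff = FOUR_POINTS @ sup.rotation.T + sup.translation - noisy
        assert sup.rmsd == pytest.approx(
            np.sqrt((diff ** 2).sum() / 4), abs=1e-12)

    def test_beats_random_rigid_search(self):
        """Least-squares optimality: no random rigid transform out of 1e5
        does better than the closed-form fit."""
        rng = np.random.default_rng(5)
        target = FOUR_POINTS + rng.normal(0, 1.0, FOUR_POINTS.shape)
        best = kabsch(FOUR_POINTS, target).rmsd
        n = 100_000
        q = rng.normal(size=(n, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        w, x, y, z = q.T
        rots = np.empty((n, 3, 3))
        rots[:, 0, 0] = 1 - 2 * (y * y + z * z)
        rots[:, 0, 1] = 2 * (x * y - w * z)
        rots[:, 0, 2] = 2 * (x * z + w * y)
        rots[:, 1, 0] = 2 * (x * y + w * z)
        rots[:, 1, 1] = 1 - 2 * (x * x + z * z)
        rots[:, 1, 2] = 2 * (y * z - w * x)
        rots[:, 2, 0] = 2 * (x * z - w * y)
        rots[:, 2, 1] = 2 * (y * z + w * x)
        rots[:, 2, 2] = 1 - 2 * (x * x + y * y)
        moved = np.einsum("nij,kj->nki", rots, FOUR_POINTS)
        # optimal translation for each rotation: align centroids
        moved += (target.mean(axis=0) - moved.mean(axis=1))[:, None, :]
        rmsds = np.sqrt(((moved - target) ** 2).sum(axis=(1, 2)) / 4)
        assert best <= rmsds.min() + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ContractError):
            kabsch(FOUR_POINTS[:2], FOUR_POINTS[:2])


class TestTMScore:
    def test_identical_chains_score_one(self, helix30):
        ca = helix30.ca_coords()
        tm, d0, _ = tm_score_fixed(ca, ca, [(i, i) for i in range(30)], 30)
        assert tm == pytest.approx(1.0, abs=1e-6)

    def test_d0_clamp_for_short_chains(self):
        # 1.24 * 5^(1/3) - 1.8 = 0.3204 < 0.5, so the floor engages
        assert tm_d0(20) == 0.5
        assert 1.24 * 5 ** (1 / 3) - 1.8 < 0.5
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8)

    def test_iterative_fit_beats_coarse_grid(self):
        """The shrinking-inlier protocol must reach at least the best TM
        found by an exhaustive coarse rotation grid."""
        rng = np.random.default_rng(8)
        a = np.cumsum(rng.normal(0, 2.0, (60, 3)), axis=0)
        b = a + rng.normal(0, 2.5, a.shape)
        pairs = [(i, i) for i in range(60)]
        tm, d0, _ = tm_score_fixed(a, b, pairs, 60)
        best_grid = 0.0
        angles = np.radians(np.arange(0, 360, 30))
        for ax in range(3):
            for ang in angles:
                c, s = np.cos(ang), np.sin(ang)
                rot = np.eye(3)
                i1, i2 = (ax + 1) % 3, (ax + 2) % 3
                rot[i1, i1] = c
                rot[i1, i2] = -s
                rot[i2, i1] = s
                rot[i2, i2] = c
                moved = a @ rot.T
                moved += b.mean(axis=0) - moved.mean(axis=0)
                d2 = ((moved - b) ** 2).sum(axis=1)
                best_grid = max(best_grid,
                                np.sum(1 / (1 + d2 / d0 ** 2)) / 60)
        assert tm >= best_grid - 0.01

    def test_symmetric_under_chain_swap(self, bundle_pair):
        fold, pert = bundle_pair
        pairs = [(i, i) for i in range(len(fold))]
        tm_ab, _, _ = tm_score_fixed(pert.ca_coords(), fold.ca_coords(),
                                     pairs, 50)
        tm_ba, _, _ = tm_score_fixed(fold.ca_coords(), pert.ca_coords(),
                                     pairs, 50)
        assert tm_ab == pytest.approx(tm_ba, abs=1e-3)

    def test_short_norm_length_rejected(self, helix30):
        with pytest.raises(ContractError):
            tm_score_fixed(helix30.ca_coords(), helix30.ca_coords(),
                           [(0, 0), (1, 1), (2, 2)], 4)


class TestAlignStructures:
    def test_self_alignment_perfect(self, bundle_pair):
        fold, _ = bundle_pair
        res = align_structures(fold, fold)
        assert res.tm_score == pytest.approx(1.0, abs=1e-6)
        assert res.aligned_identity == 1.0

    def test_perturbed_copy_recovers_truth_pairing(self, bundle_pair):
        fold, pert = bundle_pair
        res = align_structures(pert, fold)
        truth = [(i, i) for i in range(len(fold))]
        tm_truth, _, _ = tm_score_fixed(pert.ca_coords(), fold.ca_coords(),
                                        truth, len(pert))
        assert res.tm_score > 0.5
        assert res.tm_score > 0.9 * tm_truth

    def test_different_topologies_below_threshold(self, bundle_pair):
        fold, _ = bundle_pair
        spec = standard_fold_specs()["beta_hairpin_sheet"][1]
        other = make_fold(spec, random_sequence(
            spec.total_length, np.random.default_rng(2)), seed=5)
        assert align_structures(fold, other).tm_score < 0.4

    def test_refinement_never_below_seed(self, bundle_pair):
        """Greedy improvement: the reported TM is at least the TM of the
        naive gapless identity seed."""
        fold, pert = bundle_pair
        res = align_structures(pert, fold)
        seed_tm, _, _ = tm_score_fixed(pert.ca_coords(), fold.ca_coords(),
                                       [(i, i) for i in range(len(fold))],
                                       len(pert))
        assert res.tm_score >= seed_tm - 1e-9

    def test_monotone_degradation_with_noise(self, bundle_pair):
        from scipy.stats import spearmanr
        fold, _ = bundle_pair
        noises, tms = [], []
        for noise in (2.0, 8.0, 25.0):
            for seed in range(3):
                p = perturb_model(fold, noise, seed=seed)
                noises.append(noise)
                tms.append(align_structures(p, fold).tm_score)
        rho, _ = spearmanr(noises, tms)
        assert rho < 0

    def test_pairs_strictly_increasing(self, bundle_pair):
        fold, pert = bundle_pair
        res = align_structures(pert, fold)
        qs = [i for i, _ in res.pairs]
        ts = [j for _, j in res.pairs]
        assert qs == sorted(set(qs)) and ts == sorted(set(ts))


class TestLibrarySearch:
    @pytest.fixture(scope="class")
    def library(self):
        specs = standard_fold_specs()
        topo = [(specs[n][0], specs[n][1]) for n in
                ("two_helix_bundle", "beta_hairpin_sheet", "alpha_beta_plait")]
        return make_labeled_library(4, topo, seed=5)

    def test_hits_are_permutation_sorted_by_tm(self, library):
        query = library.entries[0].chain
        hits = search_library(query, library)
        assert sorted(h.entry_id for h in hits) == sorted(
            e.entry_id for e in library.entries)
        tms = [h.tm_score for h in hits]
        assert tms == sorted(tms, reverse=True)
        assert hits[0].tm_score == pytest.approx(1.0, abs=1e-6)

    def test_significance_gate_on_label_transfer(self, library):
        res = classify_by_nearest(library.entries[0].chain, library)
        assert res.significant and res.label == library.entries[0].label
        res2 = classify_by_nearest(library.entries[0].chain, library,
                                   min_tm=1.01)
        assert not res2.significant and res2.label is None

    def test_planted_topology_recovered(self, library):
        ok = n = 0
        for k, entry in enumerate(library.entries):
            query = perturb_model(entry.chain, 6.0, seed=100 + k)
            res = classify_by_nearest(query, library)
            n += 1
            ok += (res.label == entry.label)
        assert ok / n >= 0.9
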