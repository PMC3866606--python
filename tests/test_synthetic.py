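"""Generator contracts: determinism, invariants, planted-signal strength."""

import numpy as np
import pytest
from scipy.stats import chisquare

from sprotann.align import align_structures, tm_score_fixed
from sprotann.binding import tanimoto
from sprotann.errors import ContractError
from sprotann.qa import assign_secondary_structure
from sprotann.synthetic import (FoldSpec, make_compound_library,
                                make_dimer_template, make_fold,
                                make_holo_templates, make_labeled_library,
                                make_proteome, make_sprotein_sequences,
                                perturb_model, random_sequence,
                                standard_fold_specs)


class TestSequences:
    def test_count_and_length_window(self):
        recs = make_sprotein_sequences(100, (50, 100), seed=1)
        assert len(recs) == 100
        assert all(50 <= len(r) <= 100 for r in recs)

    def test_determinism(self):
        a = make_sprotein_sequences(20, seed=3)
        b = make_sprotein_sequences(20, seed=3)
        assert a == b

    def test_length_distribution_uniform(self):
        recs = make_sprotein_sequences(10_000, (50, 100), seed=2)
        lengths = np.array([len(r) for r in recs])
        counts = np.bincount(lengths, minlength=101)[50:101]
        _, p = chisquare(counts)
        assert p > 0.01

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ContractError):
            make_sprotein_sequences(0)


class TestFolds:
    def test_single_helix_spec_assigned_helical(self):
        spec = FoldSpec((("helix", 30),), "bundle")
        ch = make_fold(spec, "A" * 30, seed=1)
        ss = assign_secondary_structure(ch).classes
        assert ss.count("H") / 30 >= 0.8

    def test_hairpin_spec_gives_two_strands(self):
        spec = FoldSpec((("strand", 8), ("loop", 4), ("strand", 8)), "sheet")
        ch = make_fold(spec, "A" * 20, seed=1)
        ss = assign_secondary_structure(ch).classes
        assert ss[:8].count("E") >= 4 and ss[12:].count("E") >= 4

    def test_same_seed_identical_coordinates(self):
        spec = standard_fold_specs()["alpha_beta_plait"][1]
        seq = random_sequence(spec.total_length, np.random.default_rng(0))
        a = make_fold(spec, seq, seed=9)
        b = make_fold(spec, seq, seed=9)
        np.testing.assert_array_equal(a.ca_coords(), b.ca_coords())

    def test_folds_are_clash_free_and_valid(self):
        for seed in range(5):
            spec = standard_fold_specs()["three_helix_bundle"][1]
            seq = random_sequence(spec.total_length,
                                  np.random.default_rng(seed))
            ch = make_fold(spec, seq, seed=seed)
            ch.validate()
            ca = ch.ca_coords()
            d2 = ((ca[:, None] - ca[None]) ** 2).sum(-1)
            iu = np.triu_indices(len(ca), k=3)
            assert np.sqrt(d2[iu].min()) >= 3.5


class TestPerturbation:
    def test_zero_noise_is_tm_identity(self, helix30):
        p = perturb_model(helix30, 0.0, seed=1)
        tm, _, _ = tm_score_fixed(p.ca_coords(), helix30.ca_coords(),
                                  [(i, i) for i in range(30)], 30)
        assert tm == pytest.approx(1.0, abs=1e-6)

    def test_mean_tm_strictly_decreasing_over_noise_grid(self):
        spec = standard_fold_specs()["two_helix_bundle"][1]
        seq = random_sequence(spec.total_length, np.random.default_rng(1))
        fold = make_fold(spec, seq, seed=3)
        pairs = [(i, i) for i in range(len(fold))]
        means = []
        for noise in (2.0, 8.0, 25.0):
            tms = [tm_score_fixed(
                perturb_model(fold, noise, seed=s).ca_coords(),
                fold.ca_coords(), pairs, len(fold))[0] for s in range(20)]
            means.append(np.mean(tms))
        assert means[0] > means[1] > means[2]

    def test_small_noise_keeps_high_tm(self):
        spec = FoldSpec((("helix", 26), ("loop", 6), ("helix", 28)), "bundle")
        seq = random_sequence(60, np.random.default_rng(2))
        fold = make_fold(spec, seq, seed=4)
        pairs = [(i, i) for i in range(60)]
        high = sum(tm_score_fixed(
            perturb_model(fold, 2.0, seed=s).ca_coords(),
            fold.ca_coords(), pairs, 60)[0] > 0.7 for s in range(20))
        assert high >= 18      # >= 90% of seeds


class TestDimers:
    @pytest.fixture(scope="class")
    def dimer(self):
        specs = standard_fold_specs()
        rec = FoldSpec((("helix", 18), ("loop", 5), ("helix", 18),
                        ("loop", 5), ("helix", 18), ("loop", 5),
                        ("helix", 18)), "bundle")
        return make_dimer_template(specs["two_helix_bundle"][1], rec,
                                   seed=11, template_id="t0")

    def test_interfaces_nonempty_and_consistent(self, dimer):
        from sprotann.ppi import template_interface
        li, ri = template_interface(dimer)
        assert li == dimer.ligand_interface
        assert ri == dimer.receptor_interface
        assert len(li) >= 8 and len(ri) >= 8

    def test_no_interchain_ca_clash(self, dimer):
        la = dimer.ligand_chain.ca_coords()
        ra = dimer.receptor_chain.ca_coords()
        d2 = ((la[:, None] - ra[None]) ** 2).sum(-1)
        assert np.sqrt(d2.min()) >= 3.8

    def test_batch_satisfies_invariants(self):
        specs = standard_fold_specs()
        rec = FoldSpec((("helix", 20), ("loop", 5), ("helix", 20),
                        ("loop", 5), ("helix", 20)), "bundle")
        for s in range(8):
            name = list(specs)[s % 6]
            d = make_dimer_template(specs[name][1], rec, seed=200 + s)
            d.validate()
            d.ligand_chain.validate()
            d.receptor_chain.validate()


class TestLabeledLibrary:
    def test_within_topology_similarity_exceeds_cross(self):
        specs = standard_fold_specs()
        topo = [(specs[n][0], specs[n][1]) for n in
                ("two_helix_bundle", "beta_hairpin_sheet",
                 "alpha_beta_plait")]
        lib = make_labeled_library(4, topo, seed=7)
        within, cross = [], []
        entries = lib.entries
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                if len(entries[i].chain) < 10:
                    continue
                tm = align_structures(entries[i].chain,
                                      entries[j].chain).tm_score
                (within if entries[i].label == entries[j].label
                 else cross).append(tm)
        assert np.mean(within) > np.mean(cross)

    def test_labels_parse_and_identity_below_redundancy_cutoff(self):
        specs = standard_fold_specs()
        topo = [(specs[n][0], specs[n][1]) for n in
                ("two_helix_bundle", "helix_hairpin")]
        lib = make_labeled_library(3, topo, seed=8)
        for e in lib.entries:
            c, a, t = e.label.split(".")
            assert int(c) > 0 and int(a) > 0 and int(t) > 0
        by_label = {}
        for e in lib.entries:
            by_label.setdefault(e.label, []).append(e.chain.sequence)
        for seqs in by_label.values():
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    ident = np.mean([a == b for a, b in zip(seqs[i], seqs[j])])
                    assert ident < 0.95


class TestProteome:
    def test_zero_rate_plants_exact_copy(self):
        from sprotann.structio import SequenceRecord
        src = SequenceRecord("r", "ACDEFGHIKLMNPQRSTVWY" * 5)
        recs, truth = make_proteome(3, [src], 0.0, seed=1)
        hom = [r for r in recs if r.id == "hom_r"][0]
        assert hom.sequence == src.sequence
        assert truth == {"hom_r": "r"}

    def test_mutation_rate_governs_identity(self):
        from sprotann.structio import SequenceRecord
        src = SequenceRecord("r", "ACDEFGHIKLMNPQRSTVWY" * 10)
        idents = []
        for seed in range(10):
            recs, _ = make_proteome(0, [src], 0.3, seed=seed)
            idents.append(np.mean([a == b for a, b in
                                   zip(recs[0].sequence, src.sequence)]))
        # binomial: identity ~ 0.7, sd ~ 0.032 at n = 200
        assert 0.6 <= np.mean(idents) <= 0.8

    def test_background_dissimilar_to_receptor(self):
        from sprotann.structio import SequenceRecord
        src = SequenceRecord("r", random_sequence(
            100, np.random.default_rng(5)))
        recs, _ = make_proteome(30, [], 0.1, seed=2,
                                background_length_range=(100, 100))
        idents = [np.mean([a == b for a, b in zip(r.sequence, src.sequence)])
                  for r in recs]
        assert np.mean(idents) < 0.35


class TestCompoundLibrary:
    def test_full_similarity_reproduces_probe(self):
        lib = make_compound_library(50, n_actives=3,
                                    similarity_to_probe=1.0, seed=1)
        for cid in lib.active_ids:
            fp = lib.fingerprints[lib.ids.index(cid)]
            np.testing.assert_array_equal(fp, lib.probe)

    def test_requested_tanimoto_realized(self):
        lib = make_compound_library(200, n_actives=30,
                                    similarity_to_probe=0.8, seed=2)
        sims = [tanimoto(lib.fingerprints[lib.ids.index(c)], lib.probe)
                for c in lib.active_ids]
        assert abs(np.mean(sims) - 0.8) < 0.05

    def test_background_far_from_probe(self):
        lib = make_compound_library(300, n_actives=0,
                                    similarity_to_probe=0.9, seed=3)
        sims = [tanimoto(fp, lib.probe) for fp in lib.fingerprints]
        assert np.mean(sims) < 0.4


class TestHoloTemplates:
    def test_zn_site_surrounded_by_cys_his(self, helix30):
        spec = standard_fold_specs()["two_helix_bundle"][1]
        fold = make_fold(spec, random_sequence(
            spec.total_length, np.random.default_rng(4)), seed=6)
        hs = make_holo_templates(fold, 5, "metal", metal_type="Zn", seed=9)
        for tpl in hs.templates:
            ca = tpl.chain.ca_coords()
            d = np.linalg.norm(ca - tpl.site_position[None], axis=1)
            near = np.argsort(d)[:4]
            apt = sum(tpl.chain.sequence[i] in "CH" for i in near)
            assert apt >= 2

    def test_transferred_centers_cohere(self):
        from sprotann.binding import transfer_site_centers
        spec = standard_fold_specs()["two_helix_bundle"][1]
        fold = make_fold(spec, random_sequence(
            spec.total_length, np.random.default_rng(4)), seed=6)
        hs = make_holo_templates(fold, 5, "ligand", seed=10)
        centers = transfer_site_centers(hs.query, hs.templates)
        pts = np.array([c[0] for c in centers])
        spread = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        assert spread.max() < 8.0

    def test_same_seed_reproducible(self):
        spec = standard_fold_specs()["two_helix_bundle"][1]
        fold = make_fold(spec, random_sequence(
            spec.total_length, np.random.default_rng(4)), seed=6)
        a = make_holo_templates(fold, 3, "ligand", seed=12)
        b = make_holo_templates(fold, 3, "ligand", seed=12)
        for ta, tb in zip(a.templates, b.templates):
            np.testing.assert_array_equal(ta.chain.ca_coords(),
                                          tb.chain.ca_coords())
            np.testing.assert_array_equal(ta.site_position, tb.site_position)
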