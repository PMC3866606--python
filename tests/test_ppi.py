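"""Interaction inference: interface extraction, binding-residue scores, MCC
gating, receptor mapping, contact potential, calibration and probabilities."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from conftest import random_rigid
from sprotann.errors import CalibrationError, ContractError
from sprotann.ppi import (CalibrationModel, DimerTemplate, PotentialTable,
                          build_profile, calibrate, interaction_probability,
                          map_receptors, mcc, predict_binding_residues,
                          score_interaction, template_interface, train_pdp,
                          usable_templates)
from sprotann.structio import SequenceRecord
from sprotann.synthetic import (FoldSpec, make_dimer_template, perturb_model,
                                random_sequence, standard_fold_specs)

REC_SPEC = FoldSpec((("helix", 18), ("loop", 5), ("helix", 18), ("loop", 5),
                     ("helix", 18), ("loop", 5), ("helix", 18)), "bundle")


@pytest.fixture(scope="module")
def dimers():
    specs = standard_fold_specs()
    out = []
    for s in range(10):
        name = list(specs)[s % 6]
        out.append(make_dimer_template(specs[name][1], REC_SPEC,
                                       seed=100 + s, template_id=f"t{s}"))
    return out


class TestInterface:
    def test_recomputed_sets_match_stored_truth(self, dimers):
        li, ri = template_interface(dimers[0])
        assert li == dimers[0].ligand_interface
        assert ri == dimers[0].receptor_interface

    def test_distant_chains_empty(self, dimers):
        d = dimers[0]
        far = d.ligand_chain.transformed(np.eye(3), np.array([1000.0, 0, 0]))
        li, ri = template_interface((far, d.receptor_chain))
        assert not li and not ri

    def test_shrinking_cutoff_monotone(self, dimers):
        d = dimers[0]
        prev_l = prev_r = None
        for cutoff in (10.0, 8.0, 6.0, 4.0):
            li, ri = template_interface(d, cutoff)
            if prev_l is not None:
                assert li <= prev_l and ri <= prev_r
            prev_l, prev_r = li, ri


class TestBindingResidues:
    def test_patch_on_surface(self, helix30):
        pred = predict_binding_residues(helix30)
        assert pred.predicted_set
        assert all(pred.exposure[i] > 0.3 for i in pred.predicted_set)

    def test_scores_invariant_under_rigid_motion(self, dimers):
        chain = dimers[0].ligand_chain
        ref = predict_binding_residues(chain)
        rot, t = random_rigid(np.random.default_rng(2))
        moved = predict_binding_residues(chain.transformed(rot, t))
        np.testing.assert_allclose(moved.scores, ref.scores, atol=1e-9)
        assert moved.predicted_set == ref.predicted_set

    def test_true_interface_outscores_other_surface(self, dimers):
        diffs = []
        for d in dimers:
            pred = predict_binding_residues(d.ligand_chain)
            iface = d.ligand_interface
            other = [i for i in range(len(d.ligand_chain))
                     if pred.exposure[i] > 0.3 and i not in iface]
            if other:
                diffs.append(np.mean(pred.scores[sorted(iface)])
                             - np.mean(pred.scores[other]))
        assert np.mean(diffs) > 0

    def test_short_chain_rejected(self):
        from sprotann.structio import chain_from_torsions
        short = chain_from_torsions("A" * 10, [(-57, -47, 180)] * 10)
        with pytest.raises(ContractError):
            predict_binding_residues(short)


class TestMCC:
    def test_perfect_and_inverted(self):
        U = set(range(10))
        assert mcc({1, 2, 3}, {1, 2, 3}, U) == pytest.approx(1.0)
        assert mcc(U - {1, 2, 3}, {1, 2, 3}, U) == pytest.approx(-1.0)

    def test_worked_2x2_table(self):
        # universe 10, predicted {1..4}, reference {3..6}:
        # tp=2 fp=2 fn=2 tn=4 -> (8-4)/sqrt(4*4*6*6) = 4/24
        val = mcc(set(range(1, 5)), set(range(3, 7)), set(range(1, 11)))
        assert val == pytest.approx(4 / 24)

    def test_degenerate_marginal_is_zero(self):
        assert mcc(set(), {1}, set(range(5))) == 0.0

    def test_exhaustive_small_universe_equivalence(self):
        """Set-based MCC equals the bitmask/popcount brute force for every
        pair of subsets of an 8-element universe."""
        n = 8
        U = set(range(n))
        masks = np.arange(2 ** n, dtype=np.uint32)
        pop = np.array([bin(m).count("1") for m in range(2 ** n)])
        subsets = [frozenset(i for i in range(n) if m >> i & 1)
                   for m in range(2 ** n)]
        P = masks[:, None]
        R = masks[None, :]
        tp = pop[P & R]
        fp = pop[P & ~R & (2 ** n - 1)]
        fn = pop[~P & (2 ** n - 1) & R]
        tn = n - tp - fp - fn
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        with np.errstate(invalid="ignore", divide="ignore"):
            expected = np.where(denom > 0,
                                (tp * tn - fp * fn) / np.sqrt(denom), 0.0)
        rng = np.random.default_rng(0)
        # full row sweep plus random pairs keeps this under a second
        for pi in range(0, 2 ** n, 16):
            for ri in rng.integers(0, 2 ** n, size=32):
                assert mcc(subsets[pi], subsets[ri], U) == pytest.approx(
                    expected[pi, ri], abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ContractError):
            mcc(set(), set(), set())


class TestUsableTemplates:
    def test_gates_and_overlap_arithmetic(self, dimers):
        d = dimers[0]
        model = perturb_model(d.ligand_chain, 3.0, seed=1)
        res = usable_templates(model, [d])
        assert res and res[0][1].tm_score >= 0.4 and res[0][2] >= 0.5

    def test_tm_gate_excludes_regardless_of_overlap(self, dimers):
        d = dimers[0]
        model = perturb_model(d.ligand_chain, 3.0, seed=1)
        assert usable_templates(model, [d], tm_min=1.01) == []

    def test_worked_mcc_on_constructed_overlap(self):
        # 60 residues, |predicted| = |mapped| = 12, overlap 8:
        # tp=8 fp=4 fn=4 tn=44 -> (352-16)/sqrt(12*12*48*48) = 336/576
        val = mcc(set(range(12)), set(range(4, 16)), set(range(60)))
        assert val == pytest.approx(336 / 576)
        assert val >= 0.5

    def test_raising_thresholds_never_adds_templates(self, dimers):
        model = perturb_model(dimers[0].ligand_chain, 3.0, seed=2)
        base = usable_templates(model, dimers, tm_min=0.4, mcc_min=0.5)
        stricter_tm = usable_templates(model, dimers, tm_min=0.6, mcc_min=0.5)
        stricter_mcc = usable_templates(model, dimers, tm_min=0.4, mcc_min=0.7)
        assert len(stricter_tm) <= len(base)
        assert len(stricter_mcc) <= len(base)


class TestReceptorMapping:
    @pytest.fixture(scope="class")
    def receptor(self, dimers):
        return dimers[0].receptor_chain

    def test_own_sequence_maps_with_identity_threading(self, receptor):
        profile = build_profile([receptor.sequence])
        proteome = [SequenceRecord("self", receptor.sequence)]
        cands = map_receptors(receptor, profile, proteome, seed=1)
        assert len(cands) == 1
        assert cands[0].map_probability > 0.9
        assert all(i == j for i, j in cands[0].threading.items())

    def test_planted_homologs_recovered(self, receptor):
        from sprotann.synthetic import make_proteome
        profile = build_profile([receptor.sequence])
        rec = SequenceRecord("r", receptor.sequence)
        hits = 0
        for seed in range(10):
            proteome, _ = make_proteome(0, [rec], 0.2, seed=seed)
            cands = map_receptors(receptor, profile, proteome, seed=seed)
            hits += bool(cands)
        assert hits >= 9

    def test_background_rarely_retained(self, receptor):
        profile = build_profile([receptor.sequence])
        rng = np.random.default_rng(3)
        proteome = [SequenceRecord(f"b{i}", random_sequence(90, rng))
                    for i in range(40)]
        cands = map_receptors(receptor, profile, proteome, seed=4)
        assert len(cands) / 40 <= 0.05

    def test_out_of_window_sequences_skipped(self, receptor):
        profile = build_profile([receptor.sequence])
        proteome = [SequenceRecord("tiny", "ACDEF")]
        assert map_receptors(receptor, profile, proteome, seed=1) == []


class TestPotential:
    def test_symmetry_and_table_shape(self, dimers):
        pot = train_pdp(dimers * 3)
        for (a, b), e in pot.energies.items():
            assert a <= b
            assert pot.e(a, b) == pot.e(b, a) == e

    def test_planted_ek_preference_recovered(self):
        specs = standard_fold_specs()
        lib = []
        for s in range(30):
            name = list(specs)[s % 6]
            lib.append(make_dimer_template(
                specs[name][1], REC_SPEC, seed=500 + s,
                interface_bias={"E": 1.0},
                receptor_interface_bias={"K": 1.0}))
        pot = train_pdp(lib)
        others = [e for (a, b), e in pot.energies.items()
                  if (a, b) != ("E", "K")]
        assert pot.e("E", "K") < np.median(others)

    def test_uniform_contacts_give_near_zero_energies(self, dimers):
        # re-type the same complexes many times with uniform sequences so
        # every pair type is well sampled (large-N null)
        rng = np.random.default_rng(7)
        lib = []
        for k in range(150):
            for d in dimers:
                lib.append(DimerTemplate(
                    f"u{k}_{d.template_id}",
                    d.ligand_chain.with_sequence(
                        "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                           size=len(d.ligand_chain)))),
                    d.receptor_chain.with_sequence(
                        "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                           size=len(d.receptor_chain)))),
                    d.ligand_interface, d.receptor_interface))
        pot = train_pdp(lib)
        values = np.array(list(pot.energies.values()))
        assert np.abs(values).max() < 0.3


class TestScoringAndCalibration:
    def test_hand_arithmetic_three_contacts(self):
        from sprotann.structio import Atom, ProteinChain, Residue
        def mini_chain(cid, seq, positions):
            residues = []
            for i, (aa, p) in enumerate(zip(seq, positions), start=1):
                p = np.asarray(p, float)
                residues.append(Residue(i, aa, {
                    "N": Atom("N", "N", p + [0.0, 1.2, 0.0]),
                    "CA": Atom("CA", "C", p),
                    "C": Atom("C", "C", p + [1.2, 0.0, 0.0]),
                    "CB": Atom("CB", "C", p + [0.0, 0.0, 1.0]),
                }))
            return ProteinChain(cid, residues)
        # contacts: (L1,R1), (L1,R2), (L2,R2) -> 4 distinct interface residues
        lig = mini_chain("A", "AC", [[0, 0, 0], [3.8, 0, 0]])
        rec = mini_chain("B", "DE", [[0, 5, 0], [3.8, 5, 0]])
        energies = {("A", "D"): -1.0, ("A", "E"): -0.5, ("C", "E"): 0.2}
        table = {}
        for (a, b), e in energies.items():
            table[tuple(sorted((a, b)))] = e
        pot = PotentialTable(table, {}, 3)
        e = score_interaction(lig, "AC", rec, {0: "D", 1: "E"}, pot)
        assert e == pytest.approx((-1.0 - 0.5 + 0.2) / 4)

    def test_zero_table_gives_zero_energy(self, dimers):
        d = dimers[0]
        pot = PotentialTable({}, {}, 0)
        e = score_interaction(d.ligand_chain, d.ligand_chain.sequence,
                              d.receptor_chain,
                              dict(enumerate(d.receptor_chain.sequence)), pot)
        assert e == 0.0

    def test_no_contacts_returns_sentinel(self, dimers):
        d = dimers[0]
        far = d.ligand_chain.transformed(np.eye(3), np.array([500.0, 0, 0]))
        pot = PotentialTable({}, {}, 0)
        assert score_interaction(far, far.sequence, d.receptor_chain,
                                 dict(enumerate(d.receptor_chain.sequence)),
                                 pot) is None

    def test_gaussian_recovery_from_draws(self):
        rng = np.random.default_rng(42)
        draws = rng.normal(-0.30, 0.15, size=10_000)
        cal = calibrate(draws)
        assert abs(cal.mu - (-0.30)) < 3 * 0.15 / np.sqrt(10_000)
        assert abs(cal.sigma - 0.15) / 0.15 < 0.05

    def test_constant_input_degenerate(self):
        with pytest.raises(CalibrationError):
            calibrate([0.5] * 100)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        e = rng.normal(0, 1, 200)
        assert calibrate(e + 2.5).mu == pytest.approx(calibrate(e).mu + 2.5)

    def test_probability_reference_points(self):
        cal = CalibrationModel(mu=-0.30, sigma=0.15, n_ref=100)
        assert interaction_probability(-0.30, cal) == pytest.approx(0.5)
        assert interaction_probability(-0.45, cal) == pytest.approx(
            1 - norm.cdf(-1.0), abs=1e-9)
        assert interaction_probability(-100.0, cal) > 0.999999

    def test_probability_strictly_decreasing(self):
        cal = CalibrationModel(mu=0.0, sigma=0.2, n_ref=50)
        es = np.linspace(-1, 1, 25)
        ps = [interaction_probability(e, cal) for e in es]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        # the favorable complex outranks the weaker one
        assert interaction_probability(-0.67, cal) > interaction_probability(-0.39, cal)

    def test_reference_probabilities_ks_uniform(self):
        rng = np.random.default_rng(9)
        ref = rng.normal(-0.3, 0.12, size=2_000)
        cal = calibrate(ref)
        ps = [interaction_probability(e, cal) for e in ref]
        assert kstest(ps, "uniform").pvalue > 0.01
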