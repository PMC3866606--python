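"""Template-based protein-protein interaction inference.

The procedure mirrors the template-transfer paradigm for small-protein
interactomes:

1. predict binding residues on the small-protein model (surface-patch score);
2. align the model to the ligand chain of every dimer template; keep hits at
   TM-score >= 0.4 whose mapped template interface overlaps the predicted
   binding patch at MCC >= 0.5;
3. map each template's receptor chain onto proteome sequences by
   profile-to-sequence alignment with a shuffle null, keeping candidates at
   probability > 0.5 and threading their sequences onto the receptor
   structure;
4. score each putative complex with a quasi-chemical residue contact
   potential (per-interface-residue energy, lower is better);
5. calibrate a Gaussian on the template library's own complex scores and
   report the interaction probability p = 1 - Phi((E - mu) / sigma), calling
   an interaction when p >= 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from scipy.special import expit

from . import constants as K
from ._dp import affine_dp
from .align import AlignmentResult, align_structures, TM_SIGNIFICANCE
from .errors import CalibrationError, ContractError
from .structio import ProteinChain, SequenceRecord

__all__ = [
    "DimerTemplate", "BindingResiduePrediction", "PotentialTable",
    "CalibrationModel", "InteractionCall", "ReceptorCandidate",
    "template_interface", "predict_binding_residues", "mcc",
    "usable_templates", "build_profile", "map_receptors", "train_pdp",
    "passes_tm_gate", "passes_mcc_gate",
    "score_interaction", "calibrate", "interaction_probability",
    "build_interaction_map", "InteractionMap",
]

CONTACT_CUTOFF = 8.0          # A, CB-CB (CA for Gly) cross-chain contact
MCC_MIN = 0.5
MAP_PROBABILITY_MIN = 0.5
CALL_PROBABILITY_MIN = 0.5
BINDING_WEIGHTS = (0.5, 0.3, 0.2)   # propensity, exposure, neighborhood
EXPOSURE_RADIUS = 10.0        # A, CB neighbor count radius
SURFACE_EXPOSURE_MIN = 0.3
PATCH_FRACTION = 0.25
PROFILE_GAP_OPEN = 2.5
PROFILE_GAP_EXT = 0.3
PROFILE_N_SHUFFLES = 100
PROFILE_LOGISTIC_CENTER = 4.0  # z-score at which map probability crosses 0.5
PROFILE_LOGISTIC_SCALE = 1.0
PDP_PSEUDOCOUNT = 1.0
MIN_PDP_CONTACTS = 200


@dataclass
class DimerTemplate:
    """A two-chain complex template: shorter chain stands in for the small
    protein (ligand-template), the longer for its receptor."""

    template_id: str
    ligand_chain: ProteinChain
    receptor_chain: ProteinChain
    ligand_interface: frozenset[int]     # 0-based residue indices
    receptor_interface: frozenset[int]

    def validate(self) -> None:
        if len(self.ligand_chain) > len(self.receptor_chain):
            raise ContractError(
                f"{self.template_id}: ligand chain longer than receptor")
        if not self.ligand_interface or not self.receptor_interface:
            raise ContractError(f"{self.template_id}: empty interface set")


@dataclass
class BindingResiduePrediction:
    scores: np.ndarray                    # per-residue, unitless
    predicted_set: frozenset[int]         # 0-based indices of the top patch
    exposure: np.ndarray = field(repr=False, default=None)


@dataclass
class PotentialTable:
    """Quasi-chemical contact potential e(a,b) with background f(a)."""

    energies: dict[tuple[str, str], float]
    frequencies: dict[str, float]
    n_contacts: int

    def e(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        return self.energies.get(key, 0.0)


@dataclass
class CalibrationModel:
    mu: float
    sigma: float
    n_ref: int


@dataclass
class ReceptorCandidate:
    sequence_id: str
    template_id: str
    map_probability: float
    # proteome sequence position -> receptor residue index (both 0-based)
    threading: dict[int, int]


@dataclass
class InteractionCall:
    sprotein_id: str
    receptor_id: str
    template_id: str
    energy: float
    probability: float
    called: bool


def template_interface(dimer_or_chains, contact_cutoff: float = CONTACT_CUTOFF):
    """Interface residue sets of a two-chain complex.

    Residue pairs with CB-CB (CA for glycine/backbone-only) distance at or
    below the cutoff across the chains define both sets. Accepts a
    DimerTemplate or a (chain_a, chain_b) tuple; returns (set_a, set_b) of
    0-based indices.
    """
    if isinstance(dimer_or_chains, DimerTemplate):
        a, b = dimer_or_chains.ligand_chain, dimer_or_chains.receptor_chain
    else:
        a, b = dimer_or_chains
    ca = a.cb_coords()
    cb = b.cb_coords()
    d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
    ii, jj = np.where(d2 <= contact_cutoff * contact_cutoff)
    return frozenset(ii.tolist()), frozenset(jj.tolist())


EXPOSURE_COUNT_LO = 2    # neighbor count mapped to exposure 1 (fully exposed)
EXPOSURE_COUNT_HI = 14   # neighbor count mapped to exposure 0 (buried)


def _exposure(chain: ProteinChain) -> np.ndarray:
    """CB-neighbor-count exposure in [0, 1]; fewest neighbors -> 1.

    The linear map uses a fixed count range (2..14 neighbors within 10 A)
    rather than the per-chain extremes, so exposure is comparable across
    chains and termini do not saturate the scale.
    """
    cb = chain.cb_coords()
    d2 = ((cb[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
    counts = (d2 <= EXPOSURE_RADIUS ** 2).sum(axis=1) - 1
    expo = (EXPOSURE_COUNT_HI - counts) / (EXPOSURE_COUNT_HI - EXPOSURE_COUNT_LO)
    return np.clip(expo, 0.0, 1.0)


def predict_binding_residues(chain: ProteinChain) -> BindingResiduePrediction:
    """Surface-patch binding-residue score.

    score_i = w1 * propensity(aa_i) + w2 * exposure_i + w3 * mean over
    spatial neighbors (CB within 10 A) of the first two terms. The predicted
    set is the top 25% of surface residues (exposure > 0.3); when no residue
    qualifies as surface, the top 25% by raw score.
    """
    if len(chain) < 20:
        raise ContractError("predict_binding_residues requires >= 20 residues")
    prop_raw = np.array([K.INTERFACE_PROPENSITY.get(r.aa, 0.0) for r in chain])
    lo = min(K.INTERFACE_PROPENSITY.values())
    hi = max(K.INTERFACE_PROPENSITY.values())
    prop = (prop_raw - lo) / (hi - lo)
    expo = _exposure(chain)
    w1, w2, w3 = BINDING_WEIGHTS
    base = w1 * prop + w2 * expo
    cb = chain.cb_coords()
    d2 = ((cb[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
    nbr = d2 <= EXPOSURE_RADIUS ** 2
    neigh = (nbr @ base) / nbr.sum(axis=1)
    scores = base + w3 * neigh

    surface = np.where(expo > SURFACE_EXPOSURE_MIN)[0]
    k = max(1, math.ceil(PATCH_FRACTION * len(surface)))
    if len(surface) == 0:
        k = max(1, math.ceil(PATCH_FRACTION * len(chain)))
        order = np.argsort(-scores, kind="stable")
        chosen = order[:k]
    else:
        order = surface[np.argsort(-scores[surface], kind="stable")]
        chosen = order[:k]
    return BindingResiduePrediction(scores, frozenset(int(i) for i in chosen), expo)


def mcc(predicted, reference, universe) -> float:
    """Matthews correlation coefficient of two residue sets over a universe.

    Returns 0 when any marginal of the 2x2 table is empty (the usual
    convention for a degenerate denominator).
    """
    universe = set(universe)
    if not universe:
        raise ContractError("mcc: empty universe")
    predicted = set(predicted)
    reference = set(reference)
    if not predicted <= universe or not reference <= universe:
        raise ContractError("mcc: sets must be subsets of the universe")
    tp = len(predicted & reference)
    fp = len(predicted - reference)
    fn = len(reference - predicted)
    tn = len(universe) - tp - fp - fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def passes_tm_gate(tm: float, tm_min: float = TM_SIGNIFICANCE) -> bool:
    """Structural-significance gate: hits at TM-score >= 0.4 qualify."""
    return tm >= tm_min


def passes_mcc_gate(value: float, mcc_min: float = MCC_MIN) -> bool:
    """Interface-overlap gate: templates kept only at MCC >= 0.5."""
    return value >= mcc_min


def usable_templates(sprotein_model: ProteinChain, dimer_library,
                     tm_min: float = TM_SIGNIFICANCE, mcc_min: float = MCC_MIN,
                     prediction: BindingResiduePrediction | None = None):
    """Dimer templates usable for the given model.

    A template qualifies when its ligand chain aligns to the model at
    TM >= tm_min and its interface, mapped through the alignment onto model
    residues, overlaps the predicted binding patch at MCC >= mcc_min
    (universe: all model residues). Returns [(template, AlignmentResult,
    mcc)] sorted by TM descending.
    """
    if prediction is None:
        prediction = predict_binding_residues(sprotein_model)
    universe = range(len(sprotein_model))
    out = []
    for dimer in dimer_library:
        aln = align_structures(sprotein_model, dimer.ligand_chain)
        if not passes_tm_gate(aln.tm_score, tm_min):
            continue
        inv = {j: i for i, j in aln.pairs}   # ligand index -> model index
        mapped = {inv[j] for j in dimer.ligand_interface if j in inv}
        value = mcc(prediction.predicted_set, mapped, universe)
        if passes_mcc_gate(value, mcc_min):
            out.append((dimer, aln, value))
    out.sort(key=lambda t: (-t[1].tm_score, t[0].template_id))
    return out


# --- receptor mapping --------------------------------------------------------

_AA_INDEX = {aa: i for i, aa in enumerate(K.AMINO_ACIDS)}


def build_profile(sequences) -> np.ndarray:
    """Position log-odds profile from an equal-length homolog set.

    Rows are positions, columns the 20 standard residues; entries are
    ln(f_pos / f_background) with a one-background pseudocount.
    """
    seqs = [s.sequence if isinstance(s, SequenceRecord) else s for s in sequences]
    if not seqs:
        raise ContractError("build_profile: empty homolog set")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ContractError("build_profile: homologs must share one length")
    bg = np.array([K.BACKGROUND_FREQUENCIES[a] for a in K.AMINO_ACIDS])
    counts = np.zeros((length, 20))
    for s in seqs:
        for pos, aa in enumerate(s):
            if aa in _AA_INDEX:
                counts[pos, _AA_INDEX[aa]] += 1.0
    freqs = (counts + bg[None, :]) / (counts.sum(axis=1, keepdims=True) + 1.0)
    return np.log(freqs / bg[None, :])


def _profile_align(profile: np.ndarray, sequence: str):
    """Semi-global alignment of a sequence (rows) to profile columns."""
    idx = np.array([_AA_INDEX.get(a, -1) for a in sequence])
    # S[i, j] = profile[j, aa_i]; unknown letters score zero
    S = np.empty((len(sequence), profile.shape[0]))
    for i, a in enumerate(idx):
        S[i, :] = profile[:, a] if a >= 0 else 0.0
    ai, bj, score = affine_dp(S, PROFILE_GAP_OPEN, PROFILE_GAP_EXT, free_ends=True)
    return ai, bj, float(score)


def map_receptors(receptor_chain: ProteinChain, profile: np.ndarray,
                  proteome, template_id: str = "", seed: int = 0,
                  n_shuffles: int = PROFILE_N_SHUFFLES,
                  min_len: int = 50, max_len: int = 600) -> list[ReceptorCandidate]:
    """Map proteome sequences onto a receptor structure via its profile.

    Each sequence in [min_len, max_len] is aligned to the receptor profile;
    its score is standardized against alignments of shuffled copies
    (>= 100 shuffles, seeded) and converted to a probability with a fixed
    logistic; candidates with probability > 0.5 are retained, carrying the
    threading of sequence positions onto receptor residues.
    """
    rng = np.random.default_rng(seed)
    out: list[ReceptorCandidate] = []
    for rec in proteome:
        if not (min_len <= len(rec.sequence) <= max_len):
            continue
        ai, bj, score = _profile_align(profile, rec.sequence)
        null = np.empty(n_shuffles)
        letters = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        for s in range(n_shuffles):
            shuffled = rng.permutation(letters).tobytes().decode()
            _, _, null[s] = _profile_align(profile, shuffled)
        sd = null.std(ddof=1)
        z = (score - null.mean()) / sd if sd > 1e-12 else 0.0
        prob = float(expit((z - PROFILE_LOGISTIC_CENTER) / PROFILE_LOGISTIC_SCALE))
        if prob > MAP_PROBABILITY_MIN:
            threading = {int(i): int(j) for i, j in zip(ai, bj)}
            out.append(ReceptorCandidate(rec.id, template_id, prob, threading))
    return out


# --- contact potential -------------------------------------------------------

def _contact_pairs(chain_a: ProteinChain, chain_b: ProteinChain,
                   cutoff: float = CONTACT_CUTOFF):
    ca = chain_a.cb_coords()
    cb = chain_b.cb_coords()
    d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
    ii, jj = np.where(d2 <= cutoff * cutoff)
    return list(zip(ii.tolist(), jj.tolist()))


def train_pdp(dimer_library) -> PotentialTable:
    """Quasi-chemical contact potential from a dimer library.

    Over all cross-interface CB-CB contacts: e(a,b) = -ln[(n(a,b) + p) /
    (N f(a) f(b) m_ab g)] with pseudocount p = 1, f estimated from interface
    residues, m_ab the 2-for-heteropair multiplicity and g the pairing
    normalizer making expectations sum to N. Symmetric by construction.
    """
    dimers = list(dimer_library)
    if len(dimers) < 30:
        raise ContractError("train_pdp requires >= 30 dimers")
    pair_counts: dict[tuple[str, str], float] = {}
    res_counts: dict[str, float] = {}
    n_contacts = 0
    for dimer in dimers:
        contacts = _contact_pairs(dimer.ligand_chain, dimer.receptor_chain)
        seq_l = dimer.ligand_chain.sequence
        seq_r = dimer.receptor_chain.sequence
        iface_l = {i for i, _ in contacts}
        iface_r = {j for _, j in contacts}
        for i in iface_l:
            res_counts[seq_l[i]] = res_counts.get(seq_l[i], 0.0) + 1.0
        for j in iface_r:
            res_counts[seq_r[j]] = res_counts.get(seq_r[j], 0.0) + 1.0
        for i, j in contacts:
            a, b = sorted((seq_l[i], seq_r[j]))
            pair_counts[(a, b)] = pair_counts.get((a, b), 0.0) + 1.0
            n_contacts += 1
    if n_contacts < MIN_PDP_CONTACTS:
        raise CalibrationError(
            f"train_pdp: only {n_contacts} contacts (< {MIN_PDP_CONTACTS})")
    total_res = sum(res_counts.values())
    f = {a: res_counts.get(a, 0.0) / total_res for a in K.AMINO_ACIDS}
    # pairing normalizer: sum of N f(a) f(b) m_ab g over unordered pairs = N
    s = 0.0
    for ai, a in enumerate(K.AMINO_ACIDS):
        for b in K.AMINO_ACIDS[ai:]:
            m = 1.0 if a == b else 2.0
            s += f[a] * f[b] * m
    g = 1.0 / s if s > 0 else 1.0
    energies: dict[tuple[str, str], float] = {}
    for ai, a in enumerate(K.AMINO_ACIDS):
        for b in K.AMINO_ACIDS[ai:]:
            m = 1.0 if a == b else 2.0
            expected = n_contacts * f[a] * f[b] * m * g
            observed = pair_counts.get((a, b), 0.0) + PDP_PSEUDOCOUNT
            energies[(a, b)] = -math.log(observed / (expected + PDP_PSEUDOCOUNT))
    return PotentialTable(energies, f, n_contacts)


def score_interaction(placed_sprotein: ProteinChain, sprotein_sequence: str,
                      receptor_chain: ProteinChain, receptor_sequence_map: dict[int, str],
                      potential: PotentialTable,
                      cutoff: float = CONTACT_CUTOFF) -> float | None:
    """Per-interface-residue docking-potential score of a placed complex.

    ``placed_sprotein`` must already be superposed into the template complex
    frame; ``receptor_sequence_map`` gives the threaded amino acid for each
    receptor residue index (unthreaded positions are skipped). Returns the
    summed contact energy divided by the number of distinct interface
    residues, or None when no contact survives.
    """
    contacts = _contact_pairs(placed_sprotein, receptor_chain, cutoff)
    total = 0.0
    iface: set[tuple[str, int]] = set()
    n_used = 0
    for i, j in contacts:
        if j not in receptor_sequence_map:
            continue
        total += potential.e(sprotein_sequence[i], receptor_sequence_map[j])
        iface.add(("L", i))
        iface.add(("R", j))
        n_used += 1
    if n_used == 0:
        return None
    return total / len(iface)


def calibrate(reference_energies) -> CalibrationModel:
    """Maximum-likelihood Gaussian over reference complex scores."""
    e = np.asarray([x for x in reference_energies if x is not None and np.isfinite(x)],
                   dtype=float)
    if len(e) < 30:
        raise ContractError("calibrate requires >= 30 finite energies")
    mu, sigma = norm.fit(e)
    if sigma < 1e-6:
        raise CalibrationError("degenerate (near-constant) energy distribution")
    return CalibrationModel(float(mu), float(sigma), len(e))


def interaction_probability(energy: float, calibration: CalibrationModel) -> float:
    """Upper-tail probability 1 - Phi((E - mu)/sigma): the fraction of
    reference complexes scoring less favorably. Strictly decreasing in E."""
    return float(norm.sf((energy - calibration.mu) / calibration.sigma))


# --- proteome-scale map ------------------------------------------------------

@dataclass
class InteractionMap:
    sprotein_ids: list[str]
    receptor_ids: list[str]
    probabilities: np.ndarray     # (n_sproteins, n_receptors), NaN = no score
    calls: list[InteractionCall]

    def sprotein_promiscuity(self):
        """(sprotein id, PPI count) sorted descending."""
        counts = {}
        for c in self.calls:
            if c.called:
                counts[c.sprotein_id] = counts.get(c.sprotein_id, 0) + 1
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def receptor_promiscuity(self):
        counts = {}
        for c in self.calls:
            if c.called:
                counts[c.receptor_id] = counts.get(c.receptor_id, 0) + 1
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def build_interaction_map(sproteins, proteome, dimer_library,
                          potential: PotentialTable | None = None,
                          calibration: CalibrationModel | None = None,
                          tm_min: float = TM_SIGNIFICANCE,
                          mcc_min: float = MCC_MIN,
                          seed: int = 0) -> InteractionMap:
    """Best interaction probability for every (small protein, proteome
    sequence) pair, maximized over usable templates x receptor candidates.

    ``sproteins`` is a list of (id, ProteinChain). Potential and calibration
    are trained on the dimer library itself when not supplied.
    """
    dimers = list(dimer_library)
    if potential is None:
        potential = train_pdp(dimers)
    if calibration is None:
        refs = []
        for dimer in dimers:
            ref = score_interaction(
                dimer.ligand_chain, dimer.ligand_chain.sequence,
                dimer.receptor_chain,
                {j: aa for j, aa in enumerate(dimer.receptor_chain.sequence)},
                potential)
            if ref is not None:
                refs.append(ref)
        calibration = calibrate(refs)

    proteome = list(proteome)
    usable_per_sprotein = {
        sid: usable_templates(model, dimers, tm_min, mcc_min)
        for sid, model in sproteins}
    # receptor candidates only for templates some model can actually use
    needed = sorted({d.template_id
                     for lst in usable_per_sprotein.values()
                     for d, _, _ in lst})
    dimer_index = {d.template_id: k for k, d in enumerate(dimers)}
    candidates: dict[str, list[ReceptorCandidate]] = {}
    for tid in needed:
        dimer = dimers[dimer_index[tid]]
        profile = build_profile([dimer.receptor_chain.sequence])
        candidates[tid] = map_receptors(
            dimer.receptor_chain, profile, proteome, template_id=tid,
            seed=seed + 101 * dimer_index[tid])

    sp_ids = [sid for sid, _ in sproteins]
    rec_ids = [rec.id for rec in proteome]
    rec_pos = {rid: i for i, rid in enumerate(rec_ids)}
    prob = np.full((len(sp_ids), len(rec_ids)), np.nan)
    best_call: dict[tuple[int, int], InteractionCall] = {}
    seq_by_id = {rec.id: rec.sequence for rec in proteome}

    for si, (sid, model) in enumerate(sproteins):
        for dimer, aln, _overlap in usable_per_sprotein[sid]:
            placed = model.transformed(aln.superposition.rotation,
                                       aln.superposition.translation)
            for cand in candidates[dimer.template_id]:
                seq = seq_by_id[cand.sequence_id]
                rec_map = {j: seq[i] for i, j in cand.threading.items()}
                energy = score_interaction(placed, model.sequence,
                                           dimer.receptor_chain, rec_map, potential)
                if energy is None:
                    continue
                p = interaction_probability(energy, calibration)
                ri = rec_pos[cand.sequence_id]
                if np.isnan(prob[si, ri]) or p > prob[si, ri]:
                    prob[si, ri] = p
                    best_call[(si, ri)] = InteractionCall(
                        sid, cand.sequence_id, dimer.template_id,
                        energy, p, p >= CALL_PROBABILITY_MIN)
    calls = [best_call[k] for k in sorted(best_call)]
    return InteractionMap(sp_ids, rec_ids, prob, calls)
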