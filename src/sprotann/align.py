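"""Structure superposition, TM-score, heuristic alignment and fold-library
search with nearest-neighbor label transfer.

The TM-score is the length-normalized similarity

    TM = (1/L_norm) * sum_i 1 / (1 + (d_i / d0)^2),
    d0 = max(0.5, 1.24 * (L_norm - 15)^(1/3) - 1.8),

maximized over rigid-body transforms by iterative superposition on shrinking
inlier subsets. TM >= 0.4 marks statistically significant structural
similarity and is the gate for all label/template transfer downstream.

The heuristic aligner seeds residue correspondences from gapless threading,
secondary-structure-string alignment and best-fragment superposition, then
refines each by alternating {superpose on current pairs -> rebuild pairs by
distance-based dynamic programming}. Normalization defaults to the query
(small protein) length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dp import affine_dp
from .errors import ContractError
from .structio import ProteinChain

__all__ = [
    "Superposition", "AlignmentResult", "LibraryHit", "ClassificationResult",
    "kabsch", "tm_d0", "tm_score_fixed", "align_structures",
    "search_library", "classify_by_nearest", "TM_SIGNIFICANCE",
]

TM_SIGNIFICANCE = 0.4
GAP_OPEN = 0.6  # distance-DP gap opening; no extension penalty


@dataclass
class Superposition:
    """Rigid transform x -> R x + t minimizing RMSD of fitted pairs."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class AlignmentResult:
    """Residue correspondence with its optimized TM-score."""

    pairs: list[tuple[int, int]]        # 0-based (query, target) indices
    tm_score: float
    d0: float
    norm_length: int
    aligned_identity: float
    superposition: Superposition | None = None

    @property
    def n_aligned(self) -> int:
        return len(self.pairs)

    def mapping(self) -> dict[int, int]:
        """query index -> target index."""
        return dict(self.pairs)


@dataclass
class LibraryHit:
    entry_id: str
    label: str
    tm_score: float
    aligned_identity: float
    alignment: AlignmentResult = field(repr=False, default=None)


@dataclass
class ClassificationResult:
    query_id: str
    cath_class: int | None
    architecture: int | None
    topology: int | None
    best_hit: LibraryHit | None
    significant: bool

    @property
    def label(self) -> str | None:
        if not self.significant:
            return None
        return f"{self.cath_class}.{self.architecture}.{self.topology}"


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of A onto B (reflection excluded)."""
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ContractError("kabsch: coordinate arrays must both be (n, 3)")
    if len(A) < 3:
        raise ContractError("kabsch requires at least 3 point pairs")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = A @ R.T + t - B
    rmsd = float(np.sqrt((diff ** 2).sum() / len(A)))
    return Superposition(R, t, rmsd)


def tm_d0(norm_length: int) -> float:
    """Length-dependent TM-score distance scale, clamped below at 0.5 A."""
    if norm_length > 15:
        val = 1.24 * (norm_length - 15) ** (1.0 / 3.0) - 1.8
    else:
        val = 0.0
    return max(0.5, val)


def _tm_sum(d2: np.ndarray, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + d2 / (d0 * d0))))


def tm_score_fixed(chain_a, chain_b, pairs, norm_length: int):
    """TM-score of a fixed residue correspondence, maximized over transforms.

    ``chain_a``/``chain_b`` may be ProteinChain objects or (n, 3) CA arrays.
    Returns ``(tm_score, d0, Superposition)`` where the superposition maps
    chain A coordinates into the frame of chain B. The iterative protocol
    re-fits on shrinking inlier subsets so the result is never below the
    plain all-pair Kabsch superposition value.
    """
    if norm_length < 5:
        raise ContractError("norm_length must be >= 5")
    A = chain_a.ca_coords() if isinstance(chain_a, ProteinChain) else np.asarray(chain_a, float)
    B = chain_b.ca_coords() if isinstance(chain_b, ProteinChain) else np.asarray(chain_b, float)
    pairs = list(pairs)
    if len(pairs) < 3:
        return 0.0, tm_d0(norm_length), None
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    PA = A[ia]
    PB = B[ib]
    d0 = tm_d0(norm_length)
    npairs = len(pairs)

    best_tm = -1.0
    best_sup = None
    half = npairs // 2
    seeds = [np.arange(npairs)]
    if half >= 3:
        seeds.append(np.arange(half))
        seeds.append(np.arange(npairs - half, npairs))
        q = max(3, npairs // 4)
        mid = (npairs - q) // 2
        seeds.append(np.arange(mid, mid + q))
    d_inlier = max(d0, 3.5)
    for seed in seeds:
        subset = seed
        prev = None
        for _ in range(30):
            sup = kabsch(PA[subset], PB[subset])
            d2 = ((PA @ sup.rotation.T + sup.translation - PB) ** 2).sum(axis=1)
            tm = _tm_sum(d2, d0) / norm_length
            if tm > best_tm:
                best_tm = tm
                best_sup = sup
            cut = d_inlier
            new = np.where(d2 < cut * cut)[0]
            while len(new) < 3:
                cut += 0.5
                new = np.where(d2 < cut * cut)[0]
            if prev is not None and len(new) == len(prev) and np.all(new == prev):
                break
            prev = subset
            subset = new
    return min(best_tm, 1.0 + 1e-12), d0, best_sup


def _pairs_from_offset(n: int, m: int, offset: int) -> list[tuple[int, int]]:
    lo = max(0, -offset)
    hi = min(n, m - offset)
    return [(i, i + offset) for i in range(lo, hi)]


def _collapsed_ss(chain: ProteinChain) -> str:
    from .qa import assign_secondary_structure
    classes = assign_secondary_structure(chain).classes
    out = []
    for c in classes:
        if c in "HGI":
            out.append("H")
        elif c in "EB":
            out.append("E")
        else:
            out.append("C")
    return "".join(out)


def _ss_seed(query: ProteinChain, target: ProteinChain) -> list[tuple[int, int]]:
    sq = _collapsed_ss(query)
    st = _collapsed_ss(target)
    S = np.full((len(sq), len(st)), -1.0)
    for i, a in enumerate(sq):
        for j, b in enumerate(st):
            if a == b:
                S[i, j] = 2.0 if a != "C" else 1.0
            elif "C" in (a, b):
                S[i, j] = 0.0
            else:
                S[i, j] = -3.0
    ai, bj, _ = affine_dp(S, gap_open=2.0, gap_ext=0.5, free_ends=True)
    return list(zip(ai.tolist(), bj.tolist()))


def _fragment_seed(ca_q: np.ndarray, ca_t: np.ndarray,
                   frag: int = 15, stride: int = 2) -> list[tuple[int, int]]:
    n, m = len(ca_q), len(ca_t)
    k = min(frag, n, m)
    best = (np.inf, 0, 0)
    for i in range(0, n - k + 1, stride):
        fq = ca_q[i:i + k]
        for j in range(0, m - k + 1, stride):
            sup = kabsch(fq, ca_t[j:j + k])
            if sup.rmsd < best[0]:
                best = (sup.rmsd, i, j)
    _, i, j = best
    return [(i + s, j + s) for s in range(k)]


def _refine(ca_q, ca_t, pairs, d0, norm_length, max_iter=30):
    """Alternate superposition and distance-DP; yield every visited pair set."""
    visited = [tuple(pairs)]
    current = pairs
    for _ in range(max_iter):
        if len(current) < 3:
            break
        ia = np.array([p[0] for p in current])
        ib = np.array([p[1] for p in current])
        sup = kabsch(ca_q[ia], ca_t[ib])
        moved = ca_q @ sup.rotation.T + sup.translation
        diff = moved[:, None, :] - ca_t[None, :, :]
        d2 = (diff ** 2).sum(axis=2)
        S = 1.0 / (1.0 + d2 / (d0 * d0))
        ai, bj, _ = affine_dp(S, gap_open=GAP_OPEN, gap_ext=0.0, free_ends=True)
        new = list(zip(ai.tolist(), bj.tolist()))
        if tuple(new) == tuple(current):
            break
        current = new
        visited.append(tuple(current))
    return visited


def align_structures(query: ProteinChain, target: ProteinChain,
                     norm_length: int | None = None) -> AlignmentResult:
    """Deterministic heuristic structure alignment reporting the max-TM result.

    Normalization length defaults to the query length (per-query
    significance). Raises ContractError for chains under 10 residues.
    """
    if len(query) < 10 or len(target) < 10:
        raise ContractError("align_structures requires chains of >= 10 residues")
    L = int(norm_length) if norm_length is not None else len(query)
    d0 = tm_d0(L)
    ca_q = query.ca_coords()
    ca_t = target.ca_coords()
    n, m = len(ca_q), len(ca_t)

    seeds: list[list[tuple[int, int]]] = []
    # (a) gapless threading at all offsets, pre-ranked by quick TM
    min_ov = max(5, min(n, m) // 3)
    offset_scores = []
    for offset in range(-(m - min_ov), n - min_ov + 1):
        pr = _pairs_from_offset(n, m, offset)
        if len(pr) < 5:
            continue
        ia = np.array([p[0] for p in pr])
        ib = np.array([p[1] for p in pr])
        sup = kabsch(ca_q[ia], ca_t[ib])
        d2 = ((ca_q[ia] @ sup.rotation.T + sup.translation - ca_t[ib]) ** 2).sum(axis=1)
        offset_scores.append((_tm_sum(d2, d0) / L, offset, pr))
    offset_scores.sort(key=lambda t: -t[0])
    seeds.extend(pr for _, _, pr in offset_scores[:6])
    # (b) secondary-structure-string alignment
    ss_pairs = _ss_seed(query, target)
    if len(ss_pairs) >= 5:
        seeds.append(ss_pairs)
    # (c) best fragment pair
    seeds.append(_fragment_seed(ca_q, ca_t))

    seed_sets: set[tuple] = set()
    visited: set[tuple] = set()
    for seed in seeds:
        if len(seed) < 5:
            continue
        seed_sets.add(tuple(seed))
        for pairset in _refine(ca_q, ca_t, seed, d0, L):
            visited.add(pairset)

    def _quick_tm(pairset) -> float:
        ia = np.array([p[0] for p in pairset])
        ib = np.array([p[1] for p in pairset])
        sup = kabsch(ca_q[ia], ca_t[ib])
        d2 = ((ca_q[ia] @ sup.rotation.T + sup.translation - ca_t[ib]) ** 2).sum(axis=1)
        return _tm_sum(d2, d0) / L

    # full TM optimization for every seed (greedy-improvement guarantee) and
    # for the most promising refined pair sets; the rest are screened by a
    # single-fit TM
    extras = sorted((p for p in visited - seed_sets if len(p) >= 5),
                    key=lambda p: (-_quick_tm(p), p))[:5]
    best = AlignmentResult([], 0.0, d0, L, 0.0, None)
    for pairset in sorted(seed_sets | set(extras)):  # sorted: deterministic ties
        if len(pairset) < 5:
            continue
        tm, _, sup = tm_score_fixed(ca_q, ca_t, list(pairset), L)
        if tm > best.tm_score:
            ident = _aligned_identity(query, target, pairset)
            best = AlignmentResult(list(pairset), tm, d0, L, ident, sup)
    return best


def _aligned_identity(query: ProteinChain, target: ProteinChain, pairs) -> float:
    if not pairs:
        return 0.0
    sq, st = query.sequence, target.sequence
    same = sum(1 for i, j in pairs if sq[i] == st[j])
    return same / len(pairs)


def search_library(query: ProteinChain, library, query_id: str = "query") -> list[LibraryHit]:
    """Align the query to every library entry; hits sorted by TM descending.

    ``library`` is a LabeledFoldLibrary or any iterable of objects with
    ``chain``, ``label`` and ``entry_id`` attributes. Ties break by aligned
    identity (descending) then entry id (lexicographic).
    """
    entries = getattr(library, "entries", library)
    hits: list[LibraryHit] = []
    for entry in entries:
        aln = align_structures(query, entry.chain)
        hits.append(LibraryHit(entry.entry_id, entry.label,
                               aln.tm_score, aln.aligned_identity, aln))
    hits.sort(key=lambda h: (-h.tm_score, -h.aligned_identity, h.entry_id))
    return hits


def classify_by_nearest(query: ProteinChain, library, min_tm: float = TM_SIGNIFICANCE,
                        query_id: str = "query") -> ClassificationResult:
    """Transfer the C.A.T label of the best structural hit when TM >= min_tm."""
    hits = search_library(query, library, query_id)
    best = hits[0] if hits else None
    if best is None or best.tm_score < min_tm:
        return ClassificationResult(query_id, None, None, None, best, False)
    c, a, t = (int(x) for x in best.label.split("."))
    return ClassificationResult(query_id, c, a, t, best, True)
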