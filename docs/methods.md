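# Methods

This note documents the models, numerical choices and synthetic study
conditions behind the package, and what the passing tests do and do not
establish about real data.

## Geometry and the backbone builder

All synthetic structures derive from one ideal-geometry backbone builder
(`structio.chain_from_torsions`): bond lengths N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å, CA–CB 1.521 Å; angles N–CA–C 111.2°, CA–C–N
116.2°, C–N–CA 121.7°; CB placed by the ideal tetrahedral L-configuration
(verified against the standard vector construction to < 0.01 Å). Torsion
conventions: φ_i = C(i−1)–N(i)–CA(i)–C(i), ψ_i = N(i)–CA(i)–C(i)–N(i+1),
and ω_i is the peptide dihedral *preceding* residue i
(CA(i−1)–C(i−1)–N(i)–CA(i)); φ, ω of the first residue and ψ of the last
are undefined. Rebuilding a chain from its measured torsions is the
identity to well below 0.5°.

Canonical element torsions: helix (−57, −47), strand (−120, 120). A
strand–turn–strand chain built from ideal torsions does not close into a
hydrogen-bonded hairpin for arbitrary turn angles; the turn
(φ,ψ) = (15, −105), (−90, 10) was calibrated once by grid search over turn
torsions to maximize bridge-pattern strand assignment while keeping all
non-bonded CA pairs ≥ 3.5 Å, and is fixed in the constants table. A fully
extended 10-mer at (−120, 120) spans 29.9 Å end to end (31.1 Å at
(−135, 135)); tests assert these computed values.

## Model quality assessment

Secondary structure uses DSSP pattern rules rather than a STRIDE clone: the
class fractions reported (H, G, I, E, B, T, C) depend only on hydrogen-bond
patterns, which the electrostatic criterion captures; backbone H-bonds use
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol` with
the amide hydrogen constructed on the C(i−1)–N–CA bisector (1.0 Å from N)
and a minimum sequence separation of 2; proline donates nothing.
Side-chain-involving bonds use pure geometry (donor–acceptor ≤ 3.5 Å,
antecedent angle ≥ 90°) because synthetic side chains are CB stubs and any
planted polar atoms carry no reliable protonation geometry.

Ramachandran regions are a shipped 10°×10° grid generated from three
rectangular cores — α (φ −90..−35, ψ −70..−20), β/polyproline (φ −170..−50,
ψ 90..175), left-handed α (φ 40..80, ψ 20..70) — expanded by 20°
(additional allowed) and 45° (generously allowed) bands under a toroidal
metric; everything else is disallowed, except glycine, which is reported at
best generously allowed. This grid approximates the four-region convention
of stereochemistry checkers without re-deriving it from a structure
database; its three reference points ((−57,−47) and (−120,120) most
favored, (60,−60) disallowed for non-Gly) are asserted in tests.

Report denominators: secondary-structure fractions are over all residues;
hydrogen-bond fractions are counts per residue by category; Ramachandran
fractions are over non-glycine residues with both torsions defined. The
confidence tier thresholds (≥ 0.7 high, ≥ 0.4 moderate) apply to an
*input* expected TM-score — model ranking itself is out of scope, and the
benchmark manifest supplies the estimates.

## Structure alignment

`tm_score_fixed` maximizes TM over transforms by Kabsch fits on shrinking
inlier subsets (inlier cutoff max(d0, 3.5 Å), grown by 0.5 Å when fewer
than 3 pairs survive; seeds: all pairs, both halves, central quarter; ≤ 30
iterations). Because the all-pair fit is one of the candidates, the result
is never below the plain superposition value. `align_structures` seeds
correspondences by (a) gapless threading at all offsets, pre-ranked by
single-fit TM with the top 6 kept, (b) alignment of collapsed
secondary-structure strings (H/E/C), and (c) the best 15-residue fragment
pair (stride 2); each seed is refined by alternating superposition with
dynamic programming over the score matrix `1/(1+(d_ij/d0)²)` (gap opening
0.6, no extension, free end gaps) until the pair set is stable or 30
rounds. Every seed pair-set and the five most promising refined sets are
then fully TM-optimized and the maximum reported, which guarantees the
greedy-improvement property against any seed. Normalization defaults to
the query (small protein) length, matching per-query significance
reporting; it is an explicit argument. Ties in library search break by
aligned identity, then entry id. The DP kernel is JIT-compiled (numba)
with a pure-Python fallback.

## PPI inference

*Binding-residue score*: `0.5·propensity + 0.3·exposure + 0.2·(neighborhood
mean of both)`, with a fixed 20-entry interface propensity table
(hydrophobic/aromatic high, charged low) and exposure from the CB neighbor
count within 10 Å mapped linearly from 2 neighbors (exposed, 1.0) to 14
(buried, 0.0) — a fixed range rather than per-chain extremes so values are
comparable across chains. The predicted set is the top 25% of surface
residues (exposure > 0.3).

*Gates*: TM ≥ 0.4 and MCC ≥ 0.5, both inclusive; the MCC universe is all
residues of the model (documented choice; computing it over template-ligand
residues instead would change little on these benchmarks but is not what
this package does).

*Receptor mapping*: one profile per receptor (log-odds with one-background
pseudocount), semi-global affine alignment (open 2.5, extend 0.3) of each
50–600 aa proteome sequence, standardized against 100 seeded shuffles of
that sequence; map probability is a logistic in the z-score centered at
z = 4 with unit scale, retained when > 0.5. This is a deliberately simple
stand-in for HMM–HMM comparison that preserves the stage contract
(probability gate + threading).

*Potential*: quasi-chemical log-odds over cross-interface CB–CB ≤ 8 Å
contacts with pseudocount 1, residue frequencies from interface residues,
heteropair multiplicity 2, and a pairing normalizer g making expectations
sum to the contact count. *Energy*: contact-energy sum divided by the
number of distinct interface residues (both chains). *Calibration*:
maximum-likelihood Gaussian over the library's own complex scores;
probability is the upper tail `1 − Φ((E−μ)/σ)` — "p-value" and
"probability" are treated as this one monotone quantity. Per (model,
sequence) pair the best probability over template × candidate combinations
is kept, and p ≥ 0.5 is a call.

## Binding-site annotation

Transferred site centers are clustered by average linkage cut at 8 Å;
pocket center is the TM-weighted member mean; pocket rank is the summed
member TM. Site confidence is `logistic(4·support_fraction + 5·mean_TM − 5)`;
the intercept is required because a two-parameter logistic in two
non-negative quantities could never fall below 0.5. Screening uses the
per-bit mean of supporting-template fingerprints as consensus and the
generalized Tanimoto Σmin/Σmax; Z is the top score standardized against
the whole library's score distribution; compound-id ties break
lexicographically. Metal types are decided by TM-weighted vote (conf_type
= winning share); binding residues are chain residues with a side-chain
atom within 3 Å or CA within 6 Å of the site, filtered by a shipped
chemistry table (Zn: C,H,D,E; Ca/Mg: D,E,N,Q,S,T plus backbone O within
3.5 Å; Fe: H,C,M,Y; Cu: H,C,M; Mn/Ni/Co: H,D,E); conf_residues is the
fraction of cluster members whose own coordinating residues, mapped
through their alignments, intersect the reported set. The three channels
are independent and may sum to 3.

## The synthetic benchmark: what it emulates and what it does not

Generators are pure functions of (parameters, seed). Study conditions
(defaults of `BenchmarkParams`):

- **Dimer library, 30 complexes** (the minimum the potential/calibration
  contracts accept): 6 "strong" complexes whose interface residues are
  re-typed from a hydrophobic interface-enriched alphabet over a polar
  surface background, and 24 "weak" complexes left with their polar surface
  composition. Docking aims an exposed ligand face at the receptor and
  accepts the farthest pose with ≥ 8 interface residues per side (minimal
  contact, no CA pair < 3.8 Å). The strong/weak mixture matters: the
  Gaussian calibration on the library's own scores makes the probability of
  a pair drawn from the same distribution uniform on (0,1), so recoverable
  planted truth requires the true complexes to sit in the favorable tail —
  as strong binders do against the heterogeneous reference sets of real
  dimer libraries.
- **Small-protein models**: torsion-space Gaussian noise (default 3°,
  expected TM ≈ 0.7 — the high/moderate confidence boundary the interaction
  stage operates at) applied to strong dimers' ligand chains, plus 2
  unrelated background folds. Torsion (not Cartesian) noise preserves
  covalent geometry, so QA sees realistic backbones.
- **Proteome**: 20 random background sequences plus one homolog per strong
  receptor at 8% point mutation (≈ 92% identity) — the close-homolog regime
  that a probability > 0.5 profile gate retains; the contact potential is
  spiky enough that one hydrophobic→polar interface mutation shifts a
  complex score by its full spread, so heavily mutated homologs genuinely
  score as non-binders.
- **Holo templates**: 5 per query, 5° torsion noise, site planted 3 Å off
  the local backbone of a surface anchor (so ≥ 3 CAs coordinate), ≤ 1 Å
  site jitter, random rigid motion per template; metal templates (and the
  returned query copy) have coordinating residues re-typed to chemically
  apt identities. Metal types are drawn from a Ca/Zn/Mg-dominated mixture.
- **Compounds**: 256-bit fingerprints, background density 0.2; actives
  reach an expected Tanimoto t to the probe by swapping
  k = n₁(1−t)/(1+t) set bits.

Passing tests show the pipeline recovers planted signal under these
conditions — exact ideal geometry, single-domain monomers, point-mutation
homology, abstract fingerprints. They do not demonstrate performance on
real proteomes: real models have non-ideal geometry and missing regions,
real interfaces are not compositionally clean, real homology includes
indels and domain rearrangements, and real compound similarity is not
independent random bits. Problem sizes (30 dimers, 8 models, 26-sequence
proteome, 1,000-compound screens, 3-seed recovery grids) are the package's
chosen desk-scale study conditions.

## Numerical conventions and degenerate inputs

Angles are degrees in (−180, 180]; coordinates Å. Chains under 5 residues
assign all-coil; chains under 20 refuse binding-residue prediction; MCC
returns 0 on any empty marginal and refuses an empty universe; screening
refuses libraries under 10 compounds or with zero score variance;
calibration refuses σ < 1e-6 or fewer than 30 energies; `d0` clamps at
0.5 Å (the formula is ≤ 0.5 for normalization lengths ≤ 21). Zero-contact
complexes return a sentinel and are excluded from calls. Determinism: all
stochastic stages take explicit seeds; pipeline artifacts are stamped with
the seed and a SHA-256 hash of the canonical YAML config, and the
serialized benchmark is byte-identical across reruns. The pipeline
determinism test compares serialized benchmark trees rather than two full
pipeline reruns; stage code paths are themselves deterministic given the
benchmark and seed.

## Known limitations

π-helix beyond the i→i+5 rule, PROCHECK G-factors and model ranking are
not implemented; the aligner is not a fragment-level TM-align clone (its
TM values are conservative lower bounds); the profile mapper handles point
substitutions and short gaps, not remote homology; the contact potential
is sequence-composition-driven and carries no distance dependence; pocket
confidence parameters are fixed constants, not trained estimators.
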