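# sprotann

Structure-based function annotation of small proteins ("sproteins",
50–100 residues), built as a desk-scale, fully seeded analysis pipeline.
Genomes encode thousands of short open reading frames whose products evade
sequence-based annotation; when a structural model of such a protein exists,
its fold, interaction partners and small-molecule/metal binding sites can be
inferred by transfer from structurally similar templates. This package
implements that annotation chain — model quality assessment, nearest-neighbor
fold classification, template-based protein–protein interaction (PPI)
inference with statistical calibration, and template-transfer ligand/metal
binding-site prediction — together with generators that synthesize every
external dataset the chain consumes, so the whole method is testable without
any database downloads.

It is aimed at structural bioinformaticians who want a transparent,
re-derivable implementation of the template-transfer annotation paradigm,
and at method developers who need a planted-truth benchmark for it.

## The methods

**Structural similarity.** Chains are compared with the length-normalized
TM-score,

```
TM = (1/L) Σ_i 1 / (1 + (d_i/d0)²),   d0 = max(0.5, 1.24·(L−15)^⅓ − 1.8),
```

maximized over rigid-body transforms by iterative Kabsch superposition on
shrinking inlier subsets; `L` is the query length. TM ≥ 0.4 marks
statistically significant similarity and gates every transfer step.
A heuristic aligner (gapless threading, secondary-structure-string and
fragment seeds, refined by distance-matrix dynamic programming with gap
opening 0.6) finds the residue correspondence.

**Model QA.** Secondary structure follows DSSP-style pattern rules on
backbone hydrogen bonds (electrostatic energy
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5` kcal/mol);
stereochemistry is classified on a shipped Ramachandran region grid; model
confidence tiers follow the expected TM-score: ≥ 0.7 high, ≥ 0.4 moderate,
else low.

**PPI inference.** For each model, binding residues are predicted by a
surface-patch score; the model is aligned to the shorter ("ligand") chain of
every dimer template; templates are kept when TM ≥ 0.4 **and** the Matthews
correlation coefficient between the mapped template interface and the
predicted patch is ≥ 0.5. Template receptors are mapped onto proteome
sequences by profile alignment with a shuffle null (retained at probability
> 0.5) and threaded onto the receptor structure. Each putative complex is
scored with a quasi-chemical contact potential
`e(a,b) = −ln[(n(a,b)+1)/(N f(a) f(b) m_ab g)]` summed over interface
contacts and normalized per interface residue; a Gaussian fit (μ, σ) to the
template library's own scores converts energy to probability
`p = 1 − Φ((E−μ)/σ)`, and pairs with p ≥ 0.5 are called.

**Binding sites.** Bound-ligand centroids (or metal positions) of holo
templates are mapped through the alignments into the query frame, clustered
(average linkage, 8 Å); pockets carry a support/similarity confidence and a
consensus fingerprint used for Tanimoto virtual screening, where a Z-score
≥ 2 of the top compound marks a confident screen. Metal sites add a
TM-weighted type vote and a coordination-chemistry filter on binding
residues, with three independent confidence channels (site, residues, type).

## Worked example

```bash
python analysis/01_generate_benchmark.py --seed 1
python analysis/04_ppi_map.py --seed 1
python analysis/05_binding_sites.py --seed 1
```

prints (abridged):

```
benchmark seed=1 -> results/benchmark
  dimer templates : 30 (6 strong, 24 weak)
  sprotein models : 8
  planted PPIs    : 6
calls: 6  planted truth: 6  recovered: 6
precision: 1.00  recall: 1.00
sprot000: pocket err 1.10 A, conf 0.89, z_top 12.37
sprot000: metal Ni (true Ni), err 0.72 A, confs 0.90/1.00/1.00
```

Reading: from 8 small-protein models the pipeline calls 6 interactions with
proteome sequences, exactly the 6 planted (sprotein, receptor-homolog)
pairs, with no calls against background sequences. The first model's ligand
pocket is localized 1.1 Å from the planted site and ranked compounds give a
top Z-score of 12.4 (≥ 2 = confident); its planted metal site is recovered
0.7 Å from truth with the correct metal type at full type confidence.
`analysis/02_model_qa.py` and `analysis/03_classify_folds.py` produce the
QA fraction tables and the C.A.T fold assignments the same way.

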