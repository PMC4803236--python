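# Methods

`traitevo` quantifies how predicted structural traits of a protein family
evolve across a fixed phylogeny. The pipeline takes a rooted tree with
branch lengths, a protein multiple sequence alignment, and per-residue
prediction tracks (intrinsic-disorder propensity, three-state secondary
structure, phosphorylation score) for each unaligned sequence, and
produces site-specific evolutionary rates for four characters: DOT
(disorder↔order transitions), SLT (structured↔loop transitions), PT
(phosphosite gain/loss), and SEQ (amino-acid substitution).

## From predictions to phyletic patterns

Each sequence's per-residue track is projected onto its alignment row:
the k-th value lands in the k-th non-gap column; gap columns are missing.
Binarization rules (ties inclusive on the "present" side):

| trait | rule |
|---|---|
| disorder | propensity ≥ 0.4 → 1 (disordered), < 0.4 → 0 |
| secondary structure | H or E → 1 (structured), C → 0 (loop) |
| phosphosite | score ≥ 0.75 on Ser/Thr/Tyr → 1; otherwise 0 |

The 0.4 disorder cutoff follows the empirical recalibration of IUPred-style
propensities against experimentally verified disordered proteins; 0.75 is
the conventional high-confidence threshold for neural-network
phosphorylation scores. Non-S/T/Y residues are state 0 (absence of a
phosphosite), not missing, so the phospho matrix is defined at every
non-gap column and transition rates can be inferred over all sites. 'X'
residues are fully ambiguous for the amino-acid likelihood and
non-phosphorylatable. The result is one taxa × columns binary phyletic
matrix per trait, missing exactly at alignment gaps.

## Site-rate model

Binary traits evolve under a symmetric two-state continuous-time Markov
process: rate(0→1) = rate(1→0), stationary and root distribution
(½, ½), giving the closed form P(same) = ½(1 + e^(−2rt)). Gain/loss
asymmetry is deliberately excluded — with one overall exchange rate fixed
at 1 per branch-length unit, raw rates are identifiable only up to scale,
and the cross-trait comparable output is the z-score.

Among-site rate variation is a discretized gamma with shape α and K
equal-probability categories (K = 6 for binary traits, K = 16 for amino
acids). Category rates are the conditional means of the mean-1 gamma on
each quantile slice, renormalized so their arithmetic mean is exactly 1.
α is estimated by maximizing the equal-weight mixture likelihood over all
usable columns with a bounded golden-section search on log α ∈
[log 0.01, log 100] (tolerance 1e−6 in log α); hitting a bound logs a
warning (constant matrices, for instance, drive the estimate to the slow
boundary because constancy is likeliest under vanishing rates).

Per-site likelihoods use Felsenstein pruning with per-node rescaling of
partial likelihoods, so only genuinely impossible patterns (state change
across a zero-length branch) reach −inf; those sites are excluded and
reported. Missing leaves contribute all-ones partial vectors. The
site-specific rate is the empirical-Bayes posterior mean
r̂_i = Σ_k r_k L_ik / Σ_k L_ik under equal category priors (the posterior
mean rather than the median, so small examples have a closed form).
Profiles are z-normalized over included columns with the sample (n−1)
standard deviation: mean 0, sd 1, positive = faster than average.

Amino-acid columns use the published JTT replacement model
(`data/jtt.dat`: exchangeability counts and stationary frequencies). The
reversible generator Q_ij = S_ij π_j is scaled to one expected
substitution per unit branch length; transition matrices come from a
symmetric eigendecomposition computed once per model and cached per
(rate, branch length). Branch lengths are never re-optimized: the input
tree is treated as known, and the binary-trait process runs on the same
(amino-acid) branch-length scale — a deliberate approximation that leaves
raw trait rates on a relative scale.

## Scopes

Every profile can be computed for the whole family or for one clade: the
tree is pruned to the clade's leaves (collapsing unifurcations, summing
branch lengths so leaf-to-leaf paths are preserved) and the matrix subset
accordingly. Columns entirely missing within a scope are skipped and
carry no z-score.

## Downstream summaries

* **Gap filter** — a column is kept iff its gap fraction within the scope
  is strictly below 10% ("less than", so exactly 10% is removed).
* **Fast/slow classification** — fast iff z > 0, slow iff z < 0; z
  exactly 0 is neither (the boundary case is measure-zero and the strict
  rule keeps ALL_fast/ALL_slow conservative). ALL_fast/ALL_slow require
  the condition in every provided trait; columns lacking any trait's
  z-score are excluded from those flags.
* **Region counts** — fast-site counts per labeled region over kept
  columns, with unannotated stretches auto-labeled L1, L2, … in order;
  kept-site counts partition exactly across regions.
* **Accumulated rates** — per-site sum of z-scores across traits;
  values above 10 are flagged.
* **Disorder conservation** — fraction of sequences scored disordered
  per column with gapped sequences counted in the denominator, for
  mapping onto structures via the PDB B-factor field (all other bytes of
  the PDB file are preserved; unmapped residues get sentinel −1).
* **Consensus phosphosites** — a column is a consensus site for a group
  iff strictly more than 50% of the group's sequences (gaps included in
  the denominator) are predicted phosphorylated. The union of per-clade
  consensus sets is partitioned by exact set algebra into
  shared-by-all / pairwise-shared / clade-specific categories. A non-gap
  denominator is available behind a config flag but off by default; the
  family-level rule uses all family rows by default, and reports name the
  convention used.
* **Group statistics** — per-protein disorder fractions, Ser/Thr/Tyr
  fractions and pairwise percent identity (denominator: columns where
  both rows have residues; shorter-sequence and full-alignment
  denominators available, since published identity figures depend on this
  convention), compared across groups with a Shapiro-Wilk normality
  screen, Kruskal-Wallis omnibus (≥ 3 groups), and pairwise Mann-Whitney
  U with Bonferroni correction (raw p × number of pairwise tests, capped
  at 1).

## Synthetic data

The generator (`traitevo.synthetic`) replaces downloaded sequences and
external predictors with seeded simulations that have the statistical
structure the analysis assumes:

* clock-free pure-birth (Yule) clade subtrees rescaled to mean
  root-to-tip depth 0.6, joined as ((B, C), A) with stem branches 0.3 —
  the first clade is the outgroup, mirroring a duplication history;
* amino-acid columns evolved under the package's own JTT process
  (root drawn from stationary frequencies), K = 16, default α = 1.0;
* binary traits evolved under the symmetric two-state process, K = 6,
  default α = 0.7 per trait;
* alignment gaps from a presence/absence process on the tree (gain 0.45,
  loss 0.05 per unit branch length, stationary presence 0.9, root
  presence 0.95), so gaps are phylogenetically autocorrelated rather than
  i.i.d.;
* predictor-like tracks drawn uniformly on the truth's side of the
  binarization cutoff, on the wrong side with probability ε = 0.05;
  secondary-structure truth 1 becomes H or E with equal probability;
  phospho truth is masked to Ser/Thr/Tyr positions of the simulated
  sequences.

Presets: `tiny` (8 taxa × 60 columns, 2 clades) for fast tests;
`paper-shaped` (clades of 101/102/98 taxa, 900 columns, TAD/DBD/OD/SAM
domains with auto-linkers) matching the study-scale dataset shape. One
integer seed drives a single `numpy.random.Generator` threaded through
every draw; regeneration is byte-identical.

What the generator does **not** emulate: sequence-local autocorrelation
of disorder propensities, alignment error, length variation between
clades, predictor biases shared across traits, and lineage-specific
domain gain/loss. Passing recovery tests therefore shows the inference
machinery is correct under the model's own assumptions, not that external
predictors are accurate on real proteins.

A known property of the phospho trait under these conditions: because
phosphosite truth is masked to Ser/Thr/Tyr positions, the observed
pattern is dominated by residue identity (which evolves under the
sequence process), so PT rate recovery against the nominal phospho-trait
rates is weak by construction. DOT and SEQ, whose observed patterns are
direct functions of their own processes, recover strongly (Spearman
≈ 0.95 at study shape).

## Numerical choices and limitations

* Per-node likelihood rescaling avoids underflow at 300+ taxa.
* Transition matrices are cached per (rate, branch length) within one
  profile computation.
* z-normalization requires ≥ 2 non-constant rates; constant profiles
  raise rather than silently emitting zeros.
* Kruskal-Wallis/Mann-Whitney on identical constant groups return p = 1
  (documented boundary behavior).
* Group comparisons treat proteins as independent samples; with shared
  phylogeny this overstates significance (phylogenetic
  pseudoreplication), which is inherent to the protocol being
  implemented, not corrected here.
* The JTT likelihood was cross-checked against an independent
  phylogenetics implementation (agreement to printed precision on a
  4-taxon alignment); pruning is tested against brute-force enumeration
  over internal-node states on trees of up to 5 leaves for both engines.
* Problem sizes in the test suite and acceptance script: enumeration
  oracles on ≤ 5 leaves; parameter recovery at 30 taxa × 200–500 sites
  and at the full paper-shaped scale (301 × 900), the package's own
  choice of a study-scale benchmark.
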