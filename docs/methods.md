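# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `pepchip`.

## Readout model and normalization

The unit of data is a peptide with replicate intensities on a bounded
scanner scale (0–254). The per-peptide median x̃ᵢ over the available
replicates is the signal estimate; missing replicates (excluded spots,
encoded NaN) are simply dropped from the median, while peptides with
fewer than two surviving replicates are excluded from consistency
statistics. Training targets are

    tᵢ = ln(x̃ᵢ + 1) / ln(max_j x̃ⱼ + 1)  ∈ [0, 1],

a log transform that compresses the right-skewed intensity histogram; the
ratio of logarithms makes the formula base-invariant. The strongest
peptide maps to exactly 1 and a zero median to exactly 0. The inverse
(`back_transform`) is exp(t·ln(max+1)) − 1 and is exact to machine
precision; model evaluation uses it so that PCC is computed on the
intensity scale (SCC is invariant under the monotone map).

Replicate consistency is summarized by the regularized coefficient of
variation CoV = σ/(μ+1) — the +1 keeps near-zero spots from dominating —
and by the combined replicate correlation

    R₁₂₃ = √(R₁₂² + R₁₃² + R₂₃² − 2·R₁₂·R₁₃·R₂₃)

from the three pairwise Pearson correlations. The sample (n−1) standard
deviation is the CoV default; with triplicates the choice is material, so
it is an explicit `ddof` argument. The R₁₂₃ radicand is clamped at 0 and
the result at 1 against floating-point excursions; clamping is logged.

## Redundancy rules and partitioning

Two peptides are similar if they share a contiguous substring of ≥9
residues, or ≥11 residues in the same order (longest common subsequence;
the "same order" rule admits gaps, which is why LCS is the right
formalization — the canonical example pair ADLGSGAGAAGLA/ALGSGAAGAAFGL
attains exactly 11 with gapped matches). The similarity graph's connected
components (union-find) define clusters; transitive closure is the
conservative choice — it can merge chains of pairwise-similar peptides
into large clusters, but it can never split a similar pair across
subsets. At library scale the graph is built with a 9-mer index (exact
for the contiguous rule: two sequences share a ≥9-stretch iff they share
a 9-mer) and a residue-count-overlap prefilter (Σₐ min counts bounds the
LCS from above) followed by an exact LCS dynamic program compiled with
numba; equivalence to the plain all-pairs brute force is asserted in the
tests.

Whole clusters are dealt to subsets: shuffled (seeded), assigned to the
test set until it reaches the target fraction (default 10%), then to the
currently smallest of k folds. Peptides are sorted before shuffling, so
the partition is invariant to input order. Because clusters are atomic
the test fraction is approximate; an oversized cluster triggers a warning
rather than an error.

## Binding-core model

The primary predictor is an ensemble of single-hidden-layer networks in
the NNAlign tradition. Each of the L−8 candidate 9-mer cores of a peptide
is encoded (default: the residue-wise BLOSUM62 substitution profile,
scaled by 1/10; one-hot is a config alternative — the substitution
profile shares statistical strength between similar residues and speeds
recovery on small data) and scored by a sigmoid-hidden/sigmoid-output
network; the peptide's score is the maximum over cores. Training
minimizes squared error by minibatch SGD with the gradient flowing only
through the max-scoring core of each peptide in each step — the
alignment and the scoring function are learned jointly. Early stopping
monitors the held-out CV fold (patience 20 epochs, best weights
restored). The final model pools members across hidden sizes
({20, 40, 60} by default), random restarts, and folds; the ensemble
prediction is the unweighted mean.

The SGD step size defaults to 1.0: with a sigmoid output and squared
error the output derivative contributes a factor ≤ 0.25 and targets are
concentrated mid-range, so conventional small steps (0.05) demonstrably
underfit within a few hundred epochs, while 1.0 converges cleanly on
this loss surface. All randomness (initialization, batch order) threads
from one seed through `numpy.random.SeedSequence`, making training runs
bit-reproducible.

The optional sequence model is a single-layer GRU (hidden size 16 by
default) reading the whole 13-mer, with a sigmoid readout from the final
hidden state, trained with Adam and the same fold/early-stopping
discipline; backpropagation through time is implemented directly and
verified against finite differences in the tests. It is a compact stand-in
for recurrent architectures in this role, not a replication of any
specific published network, and it runs on one CPU at reduced scale.

Model comparison uses a non-parametric bootstrap over observation
indices: p is the fraction of resamples in which model B's correlation
with the targets is at least model A's, with exact ties counted half so
identical models give p = 0.5. The desk-scale default is 10,000
iterations; 1,000,000 (study scale) is a parameter.

## Motif extraction

A trained model's motif is estimated from its behavior, not its weights:
score a pool of random natural 13-mers (100,000 by default; 500,000 at
study scale; a proteome FASTA can replace the random source), keep the
top 1%, and align their 9-mer cores with a single-motif Gibbs sampler.
Each sweep withdraws one peptide's core from the pseudocount-smoothed
profile, scores every candidate offset by its log-odds against the
leave-one-out profile, and resamples the offset from the Boltzmann
distribution at the current temperature; the temperature anneals linearly
(1.5 → 0.05 over 100 sweeps by default). The best alignment by total KL
information content — including the initial state — is returned, so the
result never falls below its initialization. Frequencies with a flat
pseudocount (weight 1) against the background give the 9×20 log₂-odds
PSSM; information content is reported in bits. The background defaults to
uniform 1/20 (appropriate for the uniform synthetic libraries); a
proteome-derived vector can be supplied. Sequence weighting and
multi-cluster deconvolution are intentionally out of scope (single-allele
top-scorer sets are close to homogeneous).

Motifs are compared by Pearson correlation over the 180 flattened
entries, which is invariant to affine rescaling of a whole matrix but
sensitive to pattern differences.

## Frank benchmark

For a positive ligand of length w (13–19), the source protein is digested
into all L−w+1 windows; windows overlapping the training data or the
positives by ≥9 contiguous residues are excluded (9-mer index; the
ligand's own windows are always retained, otherwise the positive would
exclude itself), as are windows with non-standard residues. Every window
is scored as the maximum over its 13-mer subsequences, and

    Frank = #{windows scoring strictly above the ligand} / #windows.

Strict inequality means ties at the top still give Frank 0; the
denominator includes the ligand's own window, so a random scorer's
expectation is (N−1)/2N ≈ 0.4973 at N = 186 — the package measures this
baseline by averaging over every window designation per protein, the
exact conditional expectation given the scores, rather than one noisy
random designation. Frank is computed after exclusions (the filtered
window set is the ranking universe); if a ligand occurs multiple times,
its best-scoring occurrence defines its score. Ligand sets are optionally
filtered to those any model ranks with Frank ≤ 0.15, limiting the effect
of false-positive annotations. Model comparisons use the Wilcoxon
signed-rank test with Pratt's treatment of zero differences (zeros are
ranked, then dropped from the signed sum); raw pairwise p-values are
reported, with Bonferroni correction opt-in.

## Synthetic-data generator

The generator reproduces the statistical structure of the real
experiment, not its physics.

* **Motifs** are log₂-odds matrices of explicit per-position residue
  distributions: each anchor position gives one or two favored residues
  probability mass bg·2^strength (log-odds exactly +strength, default 3
  bits ≈ a strong class II anchor) with the remaining mass spread evenly;
  non-anchor positions are flat. Defining the motif as the PSSM of a
  genuine distribution is what makes motif recovery well-posed: the
  extraction pipeline estimates exactly this object.
* **Libraries** are uniform random 13-mers with no run of ≥4 identical
  residues (such peptides are hard to synthesize and bind
  unspecifically), distinct, deterministic per seed.
* **Intensities**: a peptide's latent signal is its maximum 9-mer window
  score (the binding-core assumption), mapped through a saturating
  logistic onto [0, 254] with the midpoint at half the motif's maximal
  score — leaving most random peptides in the low tail, which reproduces
  the right-skew that motivates the log transform. Each replicate then
  receives multiplicative log-normal noise (log-sd 0.3 by default, chosen
  so simulated triplicates show the consistency of real chip readouts:
  mean CoV ≈ 0.135, R₁₂₃ ≈ 0.99) and is clipped to the dynamic range.
  Intensities stay continuous by default; `quantize=True` rounds to the
  scanner's integer levels, at the cost of score ties. Window scores are
  rounded at 1e-9 so mathematically equal cores tie exactly regardless of
  summation order.
* **Benchmark proteins** are uniform random sequences with one implanted
  ligand carrying a core drawn from the motif's favored residues; with a
  flat motif the implants are indistinguishable from background, giving a
  negative control.

What the generator does *not* emulate: spatial chip structure, scanner
artifacts, sector effects, synthesis failures, position-of-core
preferences within the peptide, peptide-flanking effects, or any
allele's true chemistry. Passing tests therefore demonstrate that the
pipeline recovers planted structure under chip-like noise — not that it
would reach the same accuracy on any particular real allele.

## Problem sizes and numerical choices

The test suite runs the recovery experiment at 20,000 peptides with
2-fold CV, two ensemble members (hidden 20 and 40), a 100,000-peptide
scoring pool and 100 Gibbs sweeps; at this scale the extracted motif
correlates with the planted truth at PCC ≥ 0.9 and the permuted-target
control shows no signal. These sizes were chosen as the smallest at which
the statistics are stable; all of them are configuration, and the
defaults in `TrainConfig`/`RunConfig` reflect full-scale settings.
Degenerate inputs are handled explicitly: all-zero medians raise, constant
replicate columns raise (correlation undefined), constant predictions are
reported as degenerate rather than silently correlated, all-zero
difference vectors give p = 1, and top-fraction/selection ties break
lexicographically for determinism.

## Known limitations

* One model per allele dataset: no pan-allele generalization, no HLA
  pseudo-sequence input.
* All training peptides must share one length (13 in the primary
  workflow); variable lengths are handled only at benchmark time via the
  max-over-13-mers rule.
* The GRU variant is CPU-bound and intended for reduced-scale runs.
* The Gibbs aligner fits a single motif; mixed specificities (multi-allele
  data) would need deconvolution, which is out of scope.
* External predictor scores can be ingested from TSV for benchmarking,
  but no external tool is executed.
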