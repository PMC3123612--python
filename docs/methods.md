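# Methods

## Fragmentation event model

Collision-induced dissociation of a protonated peptide cleaves the
backbone amide bonds, producing complementary b (N-terminal) and y
(C-terminal) ions. The model assigns bond *i* of peptide A₁…A_L the event
intensity `v_i = α · P(A_i, A_{i+1}) · f_i` (arbitrary units):

* `P` — a 20×20 non-negative propensity matrix indexed by the residue on
  each side of the bond. It absorbs chemistry such as enhanced cleavage
  N-terminal to proline or C-terminal to acidic residues, without encoding
  any of it a priori.
* `f` — non-negative position factors over B = 10 bins of *relative* bond
  position, `bin = floor(B·(i−0.5)/(L−1))`, clamped to [0, B−1]. Relative
  binning lets peptides of every length share one f vector; it is how the
  model expresses the observed tendency of cleavage towards the middle of
  a peptide. Absolute indexing would give each length its own parameters
  and starve most bins of data.
* `α` — a single global scale. Because both training and scoring operate
  on sum-normalized intensity vectors, α is not identifiable from data; P
  and f are renormalized to mean 1 after every fit and the residual scale
  is folded into α. Multiplying the true α by any constant and refitting
  yields identical normalized predictions (tested).

**Assumptions.** Adjacent-residue context only (no mobile-proton or
longer-range effects); one shared f for all charge states; intensities
enter linearly. These match the intended use — ranking candidate peptides
for ion-trap spectra — not quantitative peak-height prediction.

## Training

The training set is built automatically from the input: PSMs passing the
XCorr/ΔCn filter are ranked by XCorr descending (ties: ΔCn descending,
then spectrum id), the top `train_size` non-decoy PSMs are selected, and
each spectrum is reduced to a per-bond observation: the most intense peak
within the matching tolerance of the singly-charged b_i m/z plus the
matching y_{L−i} peak, normalized to sum 1. PSMs matching no b/y ion at
all are dropped. Only singly-charged b/y ions contribute to training
observations.

The objective is the sum over examples of the squared difference between
the sum-normalized event vector and the observed per-bond fractions.
Normalizing both sides makes examples with different total ion current
commensurable and is the same normalization the downstream
Jensen–Shannon score applies. An example whose predicted event vector is
identically zero contributes the squared norm of its observation.
Optimization is L-BFGS-B over the 410 free parameters (P flattened plus
f) with lower bound 1e-8, analytic gradient, and the deterministic
all-ones initialization; `fit_params` returns the best-so-far parameters
with a convergence flag and never returns a fit worse than its
initialization. On 200 noiseless synthetic examples the fit drives the
objective below 1e-10 and recovers the propensity matrix with Pearson
r > 0.99 (acceptance suite).

## Neutral-loss EM

Dehydration (−H₂O, 18.011 Da) and deamination/ammonia loss (−NH₃,
17.027 Da) are modelled per residue: each occurrence of residue a in a
fragment triggers the loss independently with probability p_a, so the
fragment-level loss probability is `q = 1 − Π(1 − p_a)` (noisy-OR).
Evidence per matched fragment is `w = min(1, loss peak / parent peak)`;
the cap guards against noise peaks exceeding the parent. The E-step
assigns each residue occurrence in a loss-bearing fragment the posterior
responsibility `p_a / q`; the M-step divides summed responsibilities by
total occurrences. This is the exact EM for the noisy-OR model, chosen
over a within-fragment normalized ("exactly one cause") decomposition
precisely because it carries the standard EM guarantee: the observed-data
log-likelihood is non-decreasing at every iteration, which the test suite
asserts on every trace. For single-residue fragments one iteration closes
to the observed per-residue loss fraction. Water and ammonia are fit in
two independent runs; initialization is p = 0.05 everywhere; convergence
is max |Δp| < 1e-6; residues never seen in any fragment are reported as
NaN and flagged, not guessed.

Known limitation: when evidence is collected from predicted-spectrum-like
data, the matched parent peak is itself already loss-attenuated, so
`w = loss/parent` overestimates q (for q_w = 0.25 the ratio is ≈ 0.34).
The bias applies equally to every candidate peptide and therefore does not
affect ranking; recovery tests use directly generated observations, where
the estimator is consistent (max error ≤ 0.05 at 5000 fragments).

## Theoretical spectrum

Each event's intensity is split equally between b_i and y_{L−i}
(configurable asymmetry). Within each ion, intensity is allocated
sequentially to water then ammonia losses — `water = I·q_w`,
`ammonia = I·(1−q_w)·q_a`, `parent = I·(1−q_w)·(1−q_a)` — conserving the
event intensity exactly while staying non-negative for any probabilities.
The a ion (b − CO) rides at 0.2 × its b parent; +1/+2 isotope satellites
ride at 0.5/0.15 of each monoisotopic peak, offset 1.00335/z. The a-ion
and isotope fractions are fixed pragmatic constants adequate at ~1 Th
resolution, not fitted quantities; both are configurable and can be
disabled. Fragments are singly charged for precursor charge ≤ 2; for
charge ≥ 3 each ion's intensity is shared 70/30 between its 1+ and 2+
peaks. Masses are monoisotopic throughout (residue table from pyteomics);
I and L share one mass; cysteine is unmodified unless the fixed
carbamidomethyl flag is set. Zero-intensity peaks are not emitted, so with
loss probabilities 0, no isotopes and no a fraction the spectrum reduces
to the pure 2(L−1)-peak b/y ladder.

## Scoring and FDR

Spectra are binned at 1.0 Th (origin 0) after a square-root intensity
transform; without the transform the divergence of ion-trap spectra is
dominated by their 2–3 tallest peaks. The transform is configurable off.
The similarity is `1 − JSD` with log base 2, so scores live in [0, 1]; the
JSD base-2 choice is what bounds the divergence by 1. Degenerate (empty or
all-zero) spectra score 0 with a warning rather than raising mid-pipeline.

The FDR curve sorts PSMs by score descending and reports, at each
threshold, cumulative targets, cumulative decoys and FDR = decoys/targets
(0 when no targets). Tied scores are resolved decoy-first, so target
counts at a given FDR are never overstated; `count_at_fdr` is verified
against brute-force threshold enumeration on hundreds of random score
sets. A PSM is a decoy iff any protein reference carries the configurable
prefix (default `rev_`).

## Pipeline

`run_validation` chains pair → filter → train → (EM) → predict + score →
export. Defaults XCorr ≥ 2.0, ΔCn ≥ 0.15 and train_size = 3000 are the
reference ion-trap operating point; ΔCn for the rank-1 hit is the value
printed on the rank-2 row (standard SEQUEST semantics; 1.0 when only one
hit exists). Ranking and the exported curve use the PI score alone — no
blend with SEQUEST scores is attempted, since any combination rule would
be an extra modelling choice; the pix file preserves both score families
so users can combine them downstream. Runs are fully deterministic: no
randomness is used anywhere in the pipeline, pix floats are serialized
with exact round-trip representations, and reruns are byte-identical
(tested). Fatal errors name their stage and remove partial outputs.

## Synthetic data

The simulator defines the study conditions for every test: tryptic-like
peptides (uniform residues, C-terminal K/R, lengths 7–20, precursor charge
2), spectra rendered from a fixed ground truth — seeded gamma(2, 0.5)
bond propensities (mean 1), a middle-heavy sine-profile f, water loss 0.25
on S/T/E/D and ammonia loss 0.20 on R/K/N/Q over small backgrounds
(0.02/0.01) — plus Poisson(20) noise peaks, uniform in m/z over
[100, M+H], with exponential intensities at 10 % of the median signal
peak. Incorrect PSMs report an interior shuffle of the true peptide:
composition and termini preserved, hence isobaric — the case a
fixed-intensity model cannot separate. Half of the incorrect reports are
assigned decoy protein references, making the decoy count an unbiased
estimate of the number of incorrect targets so that decoy-estimated FDR
can be compared against the realized false-discovery proportion computed
from the truth labels. The synthetic XCorr surrogate draws
N(3.2, 0.5²) for correct and N(2.6, 0.5²) for incorrect PSMs —
deliberately overlapping, so XCorr ranking is informative but imperfect.

What the simulator does *not* emulate: real peak-shape and calibration
error, charge-state misassignment, co-eluting precursors (chimeric
spectra), modified residues, and instrument-class differences — in
particular high-accuracy QTOF spectra, whose compressed intensity
dynamics are known to suit intensity-based scoring poorly. Passing tests
therefore demonstrate correctness of the algorithms and internal
consistency of the model, not performance on any particular instrument's
data.

## Problem sizes and numerical choices

The recovery and benchmark sizes (200 noiseless training examples, 5000
EM fragments, 2000 PSMs at 50 % shuffled, 200 random score sets for the
FDR oracle) were chosen as the smallest sizes at which the estimators'
sampling error is comfortably below the assertion margins. Matching
tolerance defaults to 0.5 Th (ion-trap); within a tolerance window the
most intense peak wins. Annotation matches greedily in order of
descending predicted intensity, so a contested experimental peak goes to
the stronger predicted ion, and no experimental peak is used twice. The
discrimination check accepts |estimated FDR − realized FDP| ≤ 0.02 at the
1 % level, a ≈4σ bound for the ~9 expected false targets at that cutoff.
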