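# Methods

This note records the statistical conventions, parameter defaults and
design decisions behind `progeval`, at the level of detail a user needs
to interpret its numbers or reproduce them.

## Data model

A corpus is a set of protein sequences over the 20 canonical amino
acids, each carrying a non-empty set of term identifiers from an ordered
vocabulary; the vocabulary order is lexicographic so that all derived
matrices are bit-identical across runs. Terms live in a child→parent
directed acyclic graph (DAG). Under the true-path rule a sequence
annotated with a term implicitly carries all its ancestors;
`impute_true_path` materializes this closure and is idempotent.
Non-canonical residues (including U/B/Z/X) are rejected rather than
remapped — ambiguity codes would contaminate k-mer counts. The standard
corpus filters — canonical residues only, length ≤ 2048, a per-label
minimum support, at least one label per sequence — are applied jointly
to a fixed point, so filtering is a projection (re-filtering is a
no-op).

Splitting is deterministic given a seed: sequences whose (imputed) label
sets contain a held-out label combination are diverted to
out-of-distribution (OOD) pools before an 80/10/10 random partition;
per-label minima in validation and test are filled scarcest-label-first
before the remaining ids are assigned by fraction. Containment
(subset-match) is the default OOD routing rule, with exact-match
available behind a flag, because a combination that is a subset of a
richer annotation still exhibits the held-out function mix.

## Spectrum embedding

The feature map of order k counts all overlapping length-k substrings
(20^k features; 8000 at the default k = 3), columns in lexicographic
order. Counts are accumulated as integers and only then normalized to
unit Euclidean norm, so the inner product of two rows is the normalized
spectrum kernel value in [0, 1]. Sequences shorter than k are an error,
not a zero row — a zero row has no unit normalization. External
(precomputed) embeddings load into the same container and are accepted
by every metric; they are not re-normalized.

## MMD

The estimator is the biased V-statistic in mean-embedding form — for
the linear kernel literally the Euclidean distance between the two
sample means; for the Gaussian kernel k(u,v) = exp(−‖u−v‖²/2σ²) the
Gram-block mean with diagonals included. Only this one estimator is
offered (no U-statistic) so that a reported number is unambiguous.
Values are reported on the square-root scale, where the linear kernel on
normalized nonnegative features is bounded by √2. Numerical conventions:
MMD² is clamped at 0 before the root; σ defaults to the median pairwise
distance over the pooled sample (subsampled to 1000 points beyond that),
resolved once per comparison and recorded in the result; the
permutation test holds σ fixed across permutations and reports the
add-one estimate (1 + #{perm ≥ obs}) / (1 + n_perm). The feature-wise
Kolmogorov–Smirnov corroboration statistic is the mean over feature
columns of the two-sample KS statistic; the mean (rather than, say, the
maximum) keeps the value in [0, 1] and comparable across feature spaces
of different dimension.

## Conditional consistency

Entry (i, j) of the label-by-label MMD matrix is the distance of the
generated-for-label-i set to the real-label-j set, all subsets equalized
to a common size upstream (size and seed are recorded in the matrix for
provenance; identical real and generated corpora receive identical
subsets, so self-evaluation scores exactly MMD 0 and MRR 1). The rank of
the diagonal entry in its row uses strict-less counting with pessimistic
ties — an exactly tied competitor counts against the model — because
ranks must be deterministic on degenerate inputs even though ties are
measure-zero for continuous embeddings. MRR is invariant under any
strictly increasing transform of the matrix and lies in [1/d, 1]; a
label-blind generator has uniformly distributed ranks and expected MRR
H_d/d (≈ 0.090 at d = 50).

The hierarchy-tolerant MRR_B removes a label's *direct* DAG parents and
children from its competitor set (never the diagonal), so confusions
between adjacent functions are not penalized; exclusion of the full
ancestor/descendant closure is available behind a flag. MRR_B ≥ MRR
always; when every competitor of a label is excluded its rank is 1.

## Diversity, novelty and overfitting controls

Per-feature entropies use 1000 equal-width bins on [0, 1] — normalized
features are bounded by 1 — and natural logarithms; only differences
between generated and real sets are interpreted, so the base and bin
convention cancel. The pairwise spread statistic is the unsquared RKHS
distance √(k(x,x) + k(y,y) − 2k(x,y)), averaged over unordered pairs and
subsampled to at most 10⁶ pairs with a recorded seed. Nearest-neighbor
squared distances exclude a row's own index only when a set is compared
against itself.

Percent identity uses global alignment with unit match score, zero
mismatch and linear gap penalty −1 (no substitution matrix — the
statistic counts identity, not similarity), and divides matches by the
alignment length; an edit-distance variant (1 − edits/max-length) is
exposed because both conventions are in circulation. Reference sets are
prefiltered to the top-k most cosine-similar spectrum embeddings before
alignment. The mutagenesis ladder substitutes each site independently
with probability r by one of the 19 other residues — substitution-only,
preserving length, so rate r corresponds exactly to expected per-site
identity 1 − r against the original, free of indel ambiguity — and
reports MMD of the mutated set to a reference per rate.

OOD Top-X accuracy pools held-out real sequences with distractors,
ranks by Euclidean distance in the active embedding, breaks ties at the
X-th distance by ascending pool index, and never includes the generated
set itself in the pool.

## Generators

**n-gram.** START-padded, STOP-terminated windows; additive smoothing
α = 0.1 applied at sampling time, so every context's conditional sums
to 1. Draws shorter than 5 residues are redrawn (they cannot be
embedded at k = 3). One model per label (multilabel structure
discarded) or one per distinct exact label set.

**Conditional WGAN-GP (miniature).** The critic score is
Σᵢ (vᵢ(y)ᵀ h_{pᵢ}(x) + gᵢ(x)) with identity output activation: a shared
dense trunk, per-branch linear label projections tapping the trunk at
strictly increasing depths pᵢ, and scalar unconditional heads; an
auxiliary-classifier head shares the trunk. Labels enter as the *sum*
of one-hot term encodings (a multilabel set is one vector), sequences as
one-hot tensors with a 21st padding channel at fixed length L. The
auxiliary cross-entropy is read as per-label binary cross-entropy summed
over labels — a sum of one-hots is not a categorical target, so the
multilabel (Bernoulli-per-label) reading is the coherent one — weighted
by γ in both players' losses. The gradient penalty
λ·mean((‖∇_x D(x̂,y)‖ − 1)²) on uniform real/fake interpolates uses
λ = 10 and a 1:1 critic:generator update ratio. The generator maps
[z; y] through dense layers to per-position softmax distributions;
decoding takes the per-position argmax and truncates at the first
padding-channel argmax (falling back to ignoring the padding channel if
that would leave fewer than 5 residues). Argmax decoding is chosen over
per-position sampling to keep a trained model's output a deterministic
function of (z, y).

All differentiation runs on a small in-package reverse-mode autodiff
engine over NumPy arrays whose vector-Jacobian products are themselves
traced operations, so the second-order gradients needed by the penalty
are exact (verified against finite differences in the test suite). The
default miniature configuration — L = 48, latent 32, one hidden
generator layer and two critic layers of width 128, one projection,
γ = 2, Adam(β₁ = 0.5, β₂ = 0.9) at 10⁻³, batch 64, 1500 steps — trains
in well under a minute per run on one CPU core; it is an intentionally
small reference model for exercising the evaluation pipeline, not a
production architecture.

## Synthetic corpora

The simulator emulates exactly the structure the metrics consume: a
small layered DAG (default one root, two internal terms, four leaves;
d = 7 — the smallest shape on which hierarchy-tolerant ranking differs
from plain ranking), per-label k-mer motifs (distinct random 4-mers by
default) overwritten into i.i.d. background residues, Gaussian lengths
(default 80 ± 10, clipped to [40, 160]), leaf labels assigned by
stratified rotation (guaranteeing every label ⌊n/2d⌋ sequences), an
extra non-ancestral leaf with probability 0.1, and ancestor closure by
construction. The `signal` parameter is the per-slot insertion
probability: a sequence of length L offers ⌊L/m⌋ non-overlapping slots
for a length-m motif, divided evenly among all carried labels' motifs
and placed round-robin at uniformly chosen free offsets — so no label's
motif is starved even at signal = 1, and at signal = 0 sequences are
statistically independent of their labels. The default signal 0.5
yields strongly separated per-label k-mer distributions (real-vs-real
MRR ≈ 1) while leaving substantial background variation.

What the simulator does **not** emulate: phylogenetic correlation,
domain architecture, realistic amino-acid composition or length/label
dependence. Tests passing on this substrate demonstrate that the
metrics and generators behave as specified under controlled signal, not
that any particular model generates biologically valid proteins.

## Calibration experiments and problem sizes

The packaged experiments run at sizes chosen to give stable statistics
in seconds-to-minutes on a single CPU core: corpora of 400–1500
sequences, per-label subsets of 20–100, 200 randomization repetitions
for null calibrations (standard error of the mean MRR ≈ 0.0005 at
d = 50), and five fixed seeds × 1500 steps for the adversarial
integration run. The label-randomized negative control exploits the
linear-kernel identity MMD = ‖mean(X) − mean(Y)‖ to reduce each
repetition to a distance matrix between per-set mean embeddings; the
identity itself is verified against the full Gram-expansion oracle in
the test suite.

## Known limitations

* The linear-kernel MRR shortcut above applies only to the spectrum
  (linear) kernel; Gaussian-kernel MRR runs through the full pairwise
  path and is correspondingly slower.
* Percent-identity prefiltering by spectrum cosine can in principle miss
  the true best alignment partner when k-mer composition is misleading;
  increase `prefilter_topk` where exactness matters.
* The OBO reader handles only `id:`/`is_a:` stanzas (by design);
  relationship types such as `part_of` are ignored.
* The miniature GAN is deterministic per seed on a fixed platform, but
  bit-level reproducibility across BLAS builds is not guaranteed.
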