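# Methods

## Sequence model and feature space

Peptides are strings over the 20 canonical amino acids; nonstandard
residues (B, J, O, U, X, Z) and gap characters are rejected at validation
rather than skipped, because silently dropping a residue would shift every
downstream 5-mer offset. Each peptide of length `L ≥ 5` is decomposed into
`L − 4` overlapping windows of `k = 5` residues; the window is the unit the
first model layer classifies, and during training each window inherits its
parent peptide's class label.

The feature space over a window is the set of continuous and gapped
n-grams, `n ∈ {1,2,3}`:

* unigrams (20);
* bigrams with one gap of length 0–3 (4 × 20² = 1,600), a gap matching any
  residue;
* trigrams with each of the two inter-residue gaps in {0, 1}
  (4 × 20³ = 32,000).

Every pattern spans at most 5 positions, so the full universe of 33,620
descriptors is exactly the set of motifs observable inside one window.
Occurrence is binarised: present anywhere in the window (at least once)
scores 1. Presence is *position-independent* within the window — a
deliberate choice, since positional variants would multiply the feature
space 5-fold without adding information at this window size, and the
binarisation semantics imply occurrence, not location. The canonical text
form writes one underscore per skipped position (`K__A`), which is
unambiguous and round-trippable; vocabulary order is (size, gap pattern,
residues) and is pinned by a SHA-256 hash in the test suite. In practice
the matrix is built over the n-grams actually observed in the training
windows: all-zero columns can never be informative, so dropping them is
mathematically inert.

## Feature selection: exact permutation test

For a binary feature and a binary class contrast, any permutation test
statistic is a function of the 2×2 contingency table alone. Conditioning on
the margins, the co-occurrence count `n11` is hypergeometric under the
null, so the exact permutation p-value is

`p = Σ_c  P_hypergeom(c)  over achievable c with  IG(c) ≥ IG(n11_obs)`,

no sampling involved. The criterion statistic is information gain
(mutual information between feature and target) in natural-log units,
`IG = H(target) − H(target | feature)` with `0·log 0 ≡ 0`; the criterion is
a pluggable function so alternatives (χ², etc.) can be swapped in. Ties in
the tail are accumulated with relative tolerance 10⁻¹²: the two extremes of
a symmetric table (`c` and `n−c`) attain equal IG only up to floating-point
noise, and both must count. A constant feature or target yields statistic 0
and p = 1.

Selection runs the test per descriptor on each of the three pairwise class
contrasts (ACP/AMP, ACP/NEG, AMP/NEG), restricting rows to the two classes
involved. A descriptor is *informative* if `p < α = 10⁻⁴` in at least one
contrast — the union across contrasts, which is the inclusive reading of a
single selected pool; an intersection mode is available. No multiple-testing
correction is layered on top of the fixed α. Because the test is discrete,
p-values are super-uniform under the null (verified empirically in the
suite), so α is an upper bound on the per-test false-positive rate.

## Stacked forests

**Layer 1** is a probability random forest (default 2,000 trees,
`mtry = ⌊√p⌋`, the classification default) over the selected binary
features; class probabilities are the average of terminal-node class
frequencies across trees. **Layer 2** (default 500 trees) classifies
peptides from 22 statistics of the ordered per-class mer-probability
sequences: for each class, mean, median, min, max, population variance,
the fraction of windows with `p_c > 0.5`, and the longest consecutive run
with `p_c > 0.5` divided by the window count; plus the window count itself.
The set captures location, spread and *contiguity* — a genuine ACP tends to
produce a run of confident windows, not isolated spikes. The schema is
versioned in the model archive so alternatives can be tested.

Layer-2 training features come from layer-1 **out-of-bag** probabilities:
each training window is scored only by trees whose bootstrap excluded it.
In-sample probabilities from a 2,000-tree forest are nearly one-hot on the
training labels, which would starve layer 2 of signal and leak labels into
its inputs; OOB is the standard leakage-free alternative to refitting the
forest once per fold. Windows that end up in every bootstrap (vanishingly
rare at these tree counts) fall back to a uniform probability row and are
counted in the model metadata.

Decisions are argmax with exact ties broken toward NEG, then AMP, then ACP:
the screening use case penalises false ACP calls most, so ambiguity never
promotes a peptide toward ACP. Prediction accepts peptides longer than 50
residues with a warning (the model is trained on peptide-scale sequences,
not proteins) and reports sub-5-mer records as per-record errors rather
than failing the batch.

One master seed expands through `numpy.random.SeedSequence` into
independent per-stage streams (fold shuffle, each forest), making training
bit-reproducible; the model archive (gzip tar with a JSON manifest and
pickled forests, all archive metadata zeroed) is byte-identical across
identical runs.

## Cross-validation

Folds are stratified by length within each class: peptides are sorted by
length (ties shuffled by the seed) and dealt round-robin, so per-class fold
sizes differ by at most one and every fold sees approximately the same
length distribution — length correlates with both window count and
composition, so naive random folds would make fold metrics noisier. The CV
driver retrains per fold and reports accuracy, AU1U and KapS for the mer
layer (held-out windows scored by layer 1) and the peptide layer (full
stack), with mean, sd and se across folds (both dispersion measures are
emitted and labelled, since conventions differ).

## Metrics

AUC is rank-based (Mann–Whitney): ties count ½, which matters for the
discrete score sets forests produce. AU1U is the Hand–Till *M* measure:
for each unordered class pair {i, j}, restrict to samples of those classes,
compute Â(i|j) (AUC of the class-i probability for discriminating i from j)
and Â(j|i), average the two, then average over pairs. For two classes with
complementary probabilities this reduces to the ordinary AUC. Cohen's kappa
uses the standard `(p_o − p_e)/(1 − p_e)` with the degenerate `p_e = 1`
case defined as 1 if agreement is perfect, else 0. The binary ACP-vs-rest
mode sums the AMP and NEG probabilities into a rest score and calls ACP
only when `p_ACP > 0.5` strictly, making the boundary case deterministic;
MCC with a zero denominator factor is reported as 0 and precision with no
predicted positives as missing.

## Synthetic data generator

The generator emulates the one statistical property the classifier needs:
classes with distinct residue-frequency profiles. Residues are drawn i.i.d.
from a per-class profile — ACP-like boosted in K/L/A/F, AMP-like in G/C/K,
negative flat — with an optional class motif (defaults: `KLAK` for ACP,
`GCGC` for AMP, implant probability 0.5) written at a uniform random
admissible offset, which creates informative bigrams/trigrams beyond
composition. The profile constants are repository choices mirroring the
qualitative enrichment pattern of real ACP/AMP collections, not measured
values. Lengths are uniform on [5, 50] by default, exercising the
length-stratified folds. A `separation` knob interpolates every class
profile toward the shared background; at 0 the three classes are
statistically identical.

What the generator does *not* emulate: residue autocorrelation, amphipathic
periodicity, shared evolutionary ancestry between ACPs and AMPs, database
redundancy, or realistic length distributions. Passing the recovery checks
therefore demonstrates that the pipeline's machinery works — selection
finds planted signal, stacking aggregates it, metrics measure it — not that
real-data performance reaches any particular level.

## Verification experiments and problem sizes

The acceptance checks run at these sizes, chosen to give stable statistics
at desk scale: oracle equivalence of the extractor on 1,000 random 5-mers
against a literal try-every-descriptor-at-every-offset oracle; permutation
p-values against full enumeration of all label assignments for every
achievable table with N ≤ 12 and against a 10⁵-draw Monte-Carlo test (3 SE)
at N = 50; AU1U against exhaustive couple enumeration on instances of ≤ 30
samples. The recovery experiment uses 300 peptides per class at full
separation, a 3:1 length-stratified train/held-out split and default
hyperparameters, and requires held-out peptide-layer AU1U ≥ 0.9, KapS ≥ 0.6
and peptide-layer AU1U above the mer layer's (aggregation across windows
should help).

The **null probe** guards against stacking leakage: peptide labels of the
same separated data set are randomly permuted before training, and held-out
AU1U must stay in [0.45, 0.55] (KapS in [−0.1, 0.1]). Label permutation is
used rather than generating at separation 0 by design: with three identical
classes the discrete permutation test typically selects *nothing* at
α = 10⁻⁴ (rare n-grams cannot reach such p-values at all), which aborts
training with the zero-features error instead of exercising the stack.
Permuted labels over separated data do select features — spuriously at the
peptide level, because windows within a peptide are correlated while the
mer-level test assumes exchangeable rows — which makes it the stronger
probe: a leaky layer 2 would have ample material to memorise, yet held-out
performance must remain at chance.

## Known limitations

* QuiPT treats windows as exchangeable rows, but windows of one peptide
  overlap in 4 of 5 positions; mer-level p-values are therefore
  anti-conservative with respect to peptide-level signal. Selection
  inherits this by construction — the stacked design compensates at the
  peptide layer, but the selected pool should not be read as peptide-level
  significance.
* Training-set class imbalance is not reweighted; strongly skewed inputs
  shift both forests' priors.
* The i.i.d. generator cannot certify performance on real sequence
  collections (see above); training on curated ACP/AMP/negative FASTA sets
  is the supported route for real evaluations and works through the same
  CLI, but its metrics depend on those external data.
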