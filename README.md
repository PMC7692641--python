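# acpstack

Three-class peptide classifier separating **anticancer peptides (ACPs)**
from **antimicrobial peptides (AMPs)** and from sequences that are neither
(the negative class), with a scikit-learn-based pipeline that is fully
testable offline via a built-in synthetic data generator.

ACPs are a subset of the cationic host-defense peptides: short (typically
5–50 residues), lysine-rich, hydrophobic and amphipathic molecules that
permeabilise negatively charged membranes. Because ACPs and AMPs are
compositionally similar, binary ACP predictors struggle exactly where it
matters — telling an anticancer peptide apart from a merely antimicrobial
one. A three-class model makes that distinction explicit. The intended
users are peptide informaticians screening candidate sequences before
synthesis.

## Model

1. **Windowing.** Every peptide is cut into overlapping 5-mers
   (`L − 4` windows of length `k = 5`); sequences shorter than 5 residues
   are rejected.
2. **Gapped n-gram features.** Each 5-mer is encoded as binary occurrences
   of motifs of size *n* = 1–3: unigrams; bigrams with a gap of 0–3
   positions (a gap matches any residue, e.g. `K__A`); trigrams where each
   of the two inter-residue gaps is 0 or 1 (e.g. `K_LL`). The vocabulary
   has 20 + 4·20² + 4·20³ = 33,620 descriptors; presence is binarised
   (multiplicity and position within the window are discarded).
3. **Feature selection (QuiPT).** For each descriptor and each class pair
   (ACP/AMP, ACP/NEG, AMP/NEG) an *exact* permutation test of association
   is computed: conditioning on the margins of the 2×2 table, the
   co-occurrence count is hypergeometric under the null, so the p-value for
   the information-gain statistic is a closed-form tail sum. A descriptor
   is kept if `p < 10⁻⁴` in at least one contrast.
4. **Stacked random forests.** A 2000-tree probability forest classifies
   5-mers from the selected features; 22 summary statistics of each
   peptide's ordered mer-probability sequences (per class: mean, median,
   min, max, variance, fraction > 0.5, longest run > 0.5; plus the mer
   count) feed a 500-tree peptide-level forest that makes the final
   ACP/AMP/NEG call. Layer 2 is trained on layer-1 *out-of-bag*
   probabilities, so the stack never sees in-bag scores. Ties in the
   argmax decision resolve toward NEG, then AMP — never promoting to ACP.

Evaluation follows the usual multi-class protocol: accuracy, Cohen's kappa
(KapS) and AU1U (the Hand–Till *M* measure, i.e. the mean of all pairwise
one-vs-one AUCs), plus an ACP-vs-rest binary mode (rest = AMP + NEG
probability summed) with MCC, precision, sensitivity, specificity and AUC.

## Worked example

Generate a labelled synthetic training set, train, and predict:

```
acpstack simulate --out-fasta demo.fasta --out-labels demo_labels.tsv \
    --n-per-class 60 --seed 7
acpstack train --fasta demo.fasta --labels demo_labels.tsv \
    --out model.tar.gz --trees1 500 --trees2 200 --seed 7
acpstack predict --model model.tar.gz --input query.fasta --out pred.tsv
```

Training logs (stderr):

```
INFO acpstack.model: selected 335 informative n-grams (alpha=0.0001)
INFO acpstack.model: layer-1 OOB accuracy: 0.825
INFO acpstack: model written to model.tar.gz (335 selected n-grams, classes ['ACP', 'AMP', 'NEG'])
```

With `query.fasta` containing experimentally verified mitochondria-targeting
ACPs (shipped as `acpstack/data/mito_acps.fasta`), `pred.tsv` begins:

```
id	prob_ACP	prob_AMP	prob_NEG	decision	warnings	error
A9K	0.985	0.005	0.01	ACP
hCAP-18	0.64	0.035	0.325	ACP
HPRP-A1-TAT	1.0	0.0	0.0	ACP
KLA	1.0	0.0	0.0	ACP
```

Each row gives the three class probabilities (they sum to 1) and the argmax
decision. This demo model was trained on *synthetic* K/L/A/F-rich ACP-like
sequences, so lysine-rich query peptides such as KLA (`KLAKLAKKLAKLAK`)
score near 1.0 for ACP; probabilities from a model trained on real curated
sets will differ. `acpstack props` tabulates length, net charge
(K + R − D − E by default) and mean Kyte–Doolittle hydropathy per peptide,
e.g. `A9K: length 10, charge +1, hydropathy 1.23`.

To train on real data instead, supply one FASTA per class — for example
curated ACP/AMP benchmark collections such as the AntiCP 2.0 training and
validation sets — via `acpstack train --acp acp.fasta --amp amp.fasta
--neg neg.fasta`, and evaluate with `acpstack cv` (length-stratified
five-fold cross-validation reporting accuracy, AU1U and KapS for both the
mer and the peptide layer).

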