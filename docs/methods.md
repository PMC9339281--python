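# Methods

## The prediction problem

R-loop binding proteins (RLBPs) identified by proteomic screens form a
small, partially inconsistent positive class against the whole proteome.
`rlooppred` treats RLBP prediction as binary classification under severe
class imbalance: a consensus positive set of a few hundred proteins versus
a negative pool of every other protein with complete feature data. The
negative pool deliberately includes single-study screen hits — a protein
seen in only one screen is not consensus evidence, and keeping such
proteins eligible as negatives is what later makes "the model re-predicts
single-study hits" a meaningful enrichment statement.

## Consensus sets

Hit lists are normalized (whitespace-stripped, uppercased; optional
accession-version stripping) and treated as sets — a protein reported
twice within one study counts once. Two rules matter in practice:
`all_k` (the strict core present in every list) and `any_pair` (present in
at least two lists, equal to the union of all pairwise intersections and
therefore a superset of the core). `any_pair` is implemented by counting
study memberships, with an internal cross-check against the explicit
pairwise-union construction. Provenance (which studies contributed each
member) is retained and written alongside the set.

The identifier namespace is a genuine free choice: gene symbols and
UniProt accessions give different counts. The package normalizes but does
not translate; mixing namespaces across lists silently deflates overlaps,
and the docs warn accordingly.

## Feature table

Thirty features per protein:

| group | features | source |
|---|---|---|
| sequence | length; GRAVY; aliphatic index; 20 composition % | computed from FASTA |
| annotation | abundance (ppm); CamSol; disorder %; LCR %; PScore; phosphosite %; nucleic-acid binding (0/1) | ingested TSVs + membership list |

GRAVY is the mean per-residue Kyte–Doolittle hydropathy (scale constants
embedded from the 1982 publication), bounded by [−4.5, 4.5]. The aliphatic
index follows Ikai: X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu)) on mole
percents, range [0, 390]. Charged percentage counts D/E/K/R only —
histidine is excluded, consistent with separate positive (K/R) and
negative (D/E) panels — and is computed for distribution comparisons but
is *not* a classifier feature; the classifier's 30 columns are the ten
scalar features plus the 20-way composition.

Phosphosite data enters as a density (100 × annotated sites / length) by
default; a binary has-any-site encoding is available via a config switch
since the raw annotation is a count whose best encoding is not obvious.
Abundance stays in raw ppm — random forests are invariant to monotone
transforms, so a log transform would not change splits.

Filtering rules, in order: sequences containing letters outside the 20
standard amino acids (U, B, Z, X, \*) are rejected with a logged count
(mirroring how sequence-based solubility predictors treat them); proteins
missing any of the 30 features are dropped (complete-case analysis, also
logged); the >5,000-residue exclusion applies only to the Pfam-style
domain-count analysis (where hits are first filtered at E-value < 0.001
and counted as distinct domain names), not to classifier rows. Feature
assembly raises rather than proceeding if the positive class is empty
after filtering.

## Easy-ensemble classifier

Each ensemble member sees all positives plus `n_negatives_per_model`
negatives drawn uniformly without replacement (presets: 300 for IP-MS with
~292 positives, 100 for Prox-MS with ~101). Member *i* derives all its
randomness from `base_seed + i`: the negative sample, the 80/20 stratified
split, the CV folds, and the forest itself. This makes the entire pipeline
bit-reproducible for a fixed base seed on a fixed platform.

Per member: stratified 80/20 train/test split (stratification preserves
class balance in these small tables); `mtry` (features per split) selected
from the grid {2, 5, 10, 15} — spanning below and above √30 ≈ 5 — by mean
10-fold cross-validated ROC-AUC on the training portion; the winning
forest is refit on the full training portion; accuracy, F1, MCC and
ROC-AUC are computed on the held-out 20%. MCC is defined as 0 when a
confusion-matrix margin vanishes, F1 as 0 when the positive margin does.
Forest size (`n_trees`, default 500) is a conventional choice exposed in
the config; tuning it is not part of the method. Test portions are drawn
fresh per member rather than shared, and proteome-wide probabilities come
from the refit-on-training forest (not out-of-bag estimates).

Prediction averages the per-member positive-class probabilities with the
arithmetic mean — not a vote — and applies two thresholds: mean ≥ 0.5
(candidate) and strictly > 0.8 (high-confidence), so a protein averaging
exactly 0.8 is a candidate but not high-confidence. Means within 1e-9 of
a threshold are treated as equal to it, so float summation order cannot
flip a boundary call. No feature selection is performed: importance
analyses concentrate on abundance and nucleic-acid binding, and trimming
to those would inflate false positives, so all 30 features are kept by
design.

## Enrichment statistics

All tests are two-sided (the conservative default where sidedness is
unstated). Fisher's exact test (via `scipy.stats.fisher_exact`) sums
hypergeometric probabilities of tables as or less probable than the
observed one; the reported odds ratio is the sample ratio a·d/(b·c), ∞
when b·c = 0. Mann–Whitney U uses the exact null distribution for
tie-free samples with n₁+n₂ ≤ 20 and the tie-corrected normal
approximation otherwise; the exact/asymptotic boundary means p-values for
small samples are enumeration-exact while large-sample p-values carry the
usual O(n^-1/2) approximation error. Bonferroni adjustment is min(1, m·p);
FDR adjustment is Benjamini–Hochberg step-up. Domain-count enrichment
bins proteins at {0, 1, 2, ≥3} domains and tests each bin's 2×2 table
against the background.

## Synthetic data: what it does and does not show

The generator's defaults are the study conditions used throughout the
tests: 100 positives versus 1,000 background proteins, effect size 2,
nucleic-acid-binding rates (0.8, 0.1), lengths 80–1,200 residues. Class
shifts mirror the direction of the real comparisons: positives are longer
(half an effect-size SD on the length mean), compositionally tilted
toward D/E/K/R and away from A/V/I/L (5% relative frequency change per
effect-size unit, which simultaneously lowers GRAVY and the aliphatic
index), more disordered/abundant/soluble (a full effect-size SD on each
annotation feature; abundance is log-normal with the shift applied on the
log scale, reproducing the orders-of-magnitude heavy tail of ppm data),
more phosphorylated, and domain-richer (Poisson means 3 vs 1).

What passing tests show: the pipeline's plumbing is correct end to end,
the ensemble recovers a planted multivariate signal of realistic shape,
and it stays at chance with no false high-confidence calls when no signal
exists. What they do not show: performance on real proteomes, where
features are correlated in ways the generator does not model (the
generator draws annotation features independently given the class),
annotation databases are incomplete, and the positive class itself is
noisy. The generator also makes no attempt at realistic domain
architectures — the domain column exists to exercise the binning
statistics, nothing more.

Synthetic screen hit lists contain every true positive plus 5% background
contamination per study, so the any-two consensus is the true class plus
a small random pairwise overlap — a mild, realistic label noise for the
end-to-end runs.

## Numerical and degenerate-input choices

- Exact-test p-values compare hypergeometric weights as exact integers in
  the test oracles; the implementation matches them to 1e-8 relative.
- Confusion-metric closed forms are exact in double precision (verified to
  1e-12 against label-vector scoring).
- Empty hit lists, empty samples, negative counts, out-of-range p-values,
  missing lengths and missing feature columns all raise with messages
  naming the offending item; a cross-validation fold that would contain
  one class raises with advice to supply a larger table.
- Ensemble summary SDs use ddof=1; a 1-model ensemble therefore reports
  NaN SD, intentionally.

## Problem sizes

Unit tests run 2–3-member ensembles of 30–100 trees on proteomes of a few
hundred proteins; the end-to-end property checks use 10-member ensembles
of 100 trees at 100/1,000 proteins, sizes at which the separable-regime
and null-regime behaviour is already unambiguous. The acceptance script
uses the same 10-member/100-tree configuration.

## Known limitations

- Disorder, LCR, CamSol and PScore are ingested, never computed; the
  package's predictions inherit any bias of the upstream tools.
- No identifier translation between namespaces.
- The published consensus counts can only be reproduced exactly from the
  original supplementary hit lists, which users must supply themselves;
  the package ships with a structurally equivalent constructed family for
  verification of the set arithmetic.
- Bit-level reproducibility holds per platform/library version, not
  across BLAS or scikit-learn versions.
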