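# Methods

## Reference databases and name normalization

Metabolite and pathway reference data are plain TSV snapshots (diffable,
versionable; a `# version:` header line carries provenance into every
output). There is no remote updating: reproducibility comes from explicit
local snapshot paths. Name lookups operate on normalized strings:
lower-cased, whitespace collapsed, Unicode dashes mapped to ASCII hyphens,
and Greek letters spelled out (α→alpha, β→beta, γ→gamma). Normalization is
idempotent, so indices and queries cannot drift apart. A synonym shared by
several metabolites is kept as a *set* in the synonym index — the database
never silently discards ambiguity; resolution policy belongs to the mapper.

## Feature mapping

Mapping runs in three tiers over the residual unmapped set: exact
(normalized canonical names, plus raw accession passthrough for
HMDB/KEGG/PubChem/METLIN tokens), synonym lookup, then fuzzy matching. The
fuzzy tier computes the Levenshtein distance between normalized strings
(an in-package dynamic-programming routine; it is the quantity under test,
so it is not delegated to a library) and accepts the nearest candidate over
all canonical names and synonyms iff

    dist / max(len(query), len(candidate)) <= max_norm_dist.

`max_norm_dist` defaults to 0.2: one edit is accepted on names of five or
more characters while short random tokens are rejected. Ambiguous synonyms
and equidistant fuzzy candidates tie-break deterministically on the
lexicographically smallest HMDB accession (then the smallest matched
string), and every tie is logged. Duplicate input names are resolved once
and broadcast. The normalized-distance threshold and the tie-break are this
package's own choices; with them the mapper is fully deterministic.

## Pathway deregulation scores

For each pathway with at least `min_pathway_size = 3` mapped members, member
intensities are z-scored against the **control** samples (mean and
population SD over controls), so a deregulation score literally measures
departure from the control state, and adding a constant to any metabolite
changes nothing. Members with zero control variance are dropped; pathways
falling below the size floor are skipped with a recorded reason, never
imputed — a principal curve through a rank-0 cloud is undefined. Metabolites
with more than 20% missing values are dropped; remaining missing values are
imputed at the metabolite's observed minimum (the usual limit-of-detection
convention in metabolomics); both policies are configurable. An optional PCA
step (default on) keeps the leading components explaining ≥99% of variance,
which stabilizes curve fits in small, collinear pathways.

The principal curve is fitted with the Hastie–Stuetzle alternation:
initialize the arc-length parameter λ by projection onto the first
principal-component line; then repeatedly (i) smooth each coordinate as a
function of λ with a LOWESS scatterplot smoother (span 0.6 of the points,
no robustness iterations), (ii) re-project all samples onto the resulting
piecewise-linear curve by exact segment-wise projection, and (iii)
re-parameterize λ by cumulative arc length. A candidate curve is accepted
only if it does not increase the total squared projection distance, so the
objective is non-increasing and the final curve never does worse than the
first-PC line; iteration stops at a relative objective change below
tol = 1e-4 or after 30 iterations. Exactly collinear clouds are already
self-consistent at initialization and converge immediately.

Each sample's score is its λ, oriented so the control mean sits at the low
end (λ → λ_max − λ when controls project high) and divided by the
per-pathway maximum over the fit samples, so scores lie in [0, 1] with a
maximum of exactly 1 on the fit set. The normalization-by-maximum is the
simplest mapping consistent with a 0–1 score range and is this package's
choice.

**Hold-out discipline.** Curves, standardization parameters, PCA bases,
orientation and normalization constants are fitted on training samples only
and frozen; held-out samples are pushed through the stored transform and
clipped to [0, 1]. A `fit_on = all` mode exists for exploratory heat maps of
every sample (the mode is recorded in the run manifest), but the default is
`train` to keep the classification stage leakage-free.

Heat-map ordering clusters pathways by average-linkage hierarchical
clustering on Euclidean distances and groups samples by phenotype, clustered
within each group; orders are exported, rendering is left to the user.

## Feature selection

Information gain on a continuous score requires discretization. The default
is Fayyad–Irani MDL: recursive entropy-minimizing binary splits, each
accepted only if the information it adds exceeds its description cost.
The MDL stop zeroes out uninformative features, which is what produces the
small selected sets this approach is known for; an equal-frequency
fallback (⌈√n⌉ bins) is available. Scores are reported in bits —
information gain is bounded by H(labels) ≤ 1 bit for a binary phenotype, so
both scores live on a [0, 1] display scale. Selection keeps every feature
with score > 0, capped at `top_k = 20`, ties broken by pathway id. When
nothing scores above zero the pipeline warns and falls back to the top five
ranked pathways so the classification stage still runs.

Information gain computed on MDL bins is invariant under monotone injective
transforms of the feature (cut points move, bin memberships do not), which
the tests check directly.

## Classification and evaluation

Seven classifiers run over small fixed tuning grids by stratified n-fold
cross-validation (default 10 folds, automatically reduced with a warning
when a class is smaller than the fold count), maximizing AUC, then refit on
the full training split:

| algorithm | implementation | grid |
|---|---|---|
| LDA | scikit-learn `LinearDiscriminantAnalysis` | — |
| SVM | sigmoid-calibrated RBF `SVC` | C ∈ {0.25, 1, 4}, γ ∈ {1/p, 2/p} |
| RF | `RandomForestClassifier` (100 trees) | max_features ∈ {⌈√p⌉, ⌈p/3⌉, p} |
| RPART | `DecisionTreeClassifier` | ccp_alpha ∈ {0.001, 0.01, 0.1} |
| PAM | in-package nearest shrunken centroids | 10 thresholds spanning [0, max shrinkage] |
| LOG | `LogisticRegression`, light L2 (λ = 1e-3) | — |
| GBM | `GradientBoostingClassifier` (lr 0.1) | trees ∈ {50, 100, 200}, depth ∈ {1, 2, 3} |

PAM is implemented directly: class centroids of features standardized by the
pooled within-class SD (plus the median offset s0) are soft-thresholded
toward the overall centroid; at threshold 0 it reduces to nearest-centroid
classification on standardized features, which the tests verify against an
independent nearest-centroid implementation.

AUC is trapezoidal over the ROC points (threshold-free); sensitivity,
specificity, F1 and balanced accuracy use the fixed probability threshold
0.5 with the non-control phenotype as the positive class. Feature importance
is permutation-based — mean AUC drop over 20 per-feature shufflings,
negative drops floored at 0, max-normalized to 1 — because it is the only
definition comparable across all seven model families. The best model is the
AUC argmax with ties broken by the fixed order LDA < SVM < RF < RPART < PAM
< LOG < GBM. All randomness (splits, folds, permutations, classifier
internals) derives from one master seed, and the end-to-end run is
byte-reproducible; output files therefore carry no timestamps.

**Clinical calibration.** Covariates are one-hot encoded where categorical,
min-max scaled to [0, 1] on training extremes (test values clipped), so they
are commensurate with PDS scores; constant covariates are dropped with a
warning. Three models — pathways only, clinical only, combined — are trained
with the best algorithm on the same split, and a Pearson correlation matrix
over clinical + selected-pathway variables is exported (zero-variance
variables flagged, correlation recorded as 0).

## Synthetic data

The generator emulates the structure the pipeline assumes: a two-class
metabolite×sample intensity matrix with pathway-level deregulation planted
in known pathways. Base intensities are log-normal (log-scale baseline mean
10, between-metabolite SD 1, per-sample noise SD 1) to mimic the positivity
and right skew of metabolomics data; effects are applied on the log scale as
`effect_size` × noise-SD shifts of the case mean of member metabolites, i.e.
`effect_size` is a standardized (Cohen's d) log-scale effect. Missingness is
injected completely at random. Name corruption (synonym swap, or typos at an
exact edit distance k) exercises the mapper tiers. Toy reference databases
use HMDB-style accessions in a reserved synthetic range (HMDB9…); for
recovery experiments memberships are generated *disjoint* so that planted
deregulation cannot bleed into overlapping pathways and ground truth stays
well-defined — with overlap allowed, a deregulated member legitimately
deregulates every pathway containing it.

What the generator does **not** emulate: batch effects and instrument drift,
correlated metabolite blocks beyond pathway membership, informative
missingness, label noise, and realistic pathway-size distributions. Passing
recovery tests therefore show that the transform and selector find planted
pathway-level mean shifts under clean conditions; they do not certify
performance on real cohorts.

## Study conditions and problem sizes

The default synthetic study — also recomputed by `scripts/acceptance.py` —
uses 60 cases / 60 controls, 80 metabolites, 20 disjoint 4-member pathways
with 3 deregulated at 2.5 SD. Under those conditions the deregulated
pathways carry the largest case–control mean-PDS gaps in ≥90% of seeds, the
selector places 3 planted informative features among 50 in the top 3 ranks
in ≥90% of seeds, and the anti-leakage null check (permuted labels, 300
samples, 60/40 split) keeps every algorithm's hold-out AUC in [0.3, 0.7] in
≥90% of seeds. The edit-distance routine is checked against a brute-force
recursive oracle exhaustively over all string pairs of length ≤4 on a
three-letter alphabet plus a seeded sample of 2,000 longer pairs (≤7), with
an additional cross-check against an independent alignment library on longer
random strings; the enumeration depth balances coverage against suite
runtime. The end-to-end recovery test runs 5 pipeline seeds; the per-stage
recovery tests carry the 25-seed versions.

## Numerical choices and degenerate inputs

- z-scoring uses population (ddof = 0) control SD; members with control SD
  ≤ 1e-12 are treated as constant and dropped.
- Curve vertices closer than 1e-12 are merged; a cloud whose points are all
  identical, or that collapses to a single location on the first PC, raises
  a degenerate-cloud error and the pathway is skipped with that reason.
- A pathway whose maximum oriented λ is ≤ 1e-12 (no spread along the curve)
  is skipped as `zero_spread`.
- Entropy uses 0·log 0 = 0; gain ratio is defined as 0 when the intrinsic
  value is 0; MDL candidate cuts are midpoints between distinct adjacent
  values.
- Grid-search ties keep the first grid point in sorted parameter order;
  best-model ties keep the earlier algorithm in the fixed order.

## Known limitations

- Binary phenotypes only; multi-class and survival endpoints are out of
  scope, as is wrapper/embedded feature selection.
- The curve fit is the core Hastie–Stuetzle alternation; the
  stability/subsampling machinery some PDS implementations add on top is not
  included.
- Fuzzy mapping reports only the single best match per name; mass- or
  formula-based matching is not attempted.
- Reference databases are vendored snapshots; building them from upstream
  dumps is out of scope.
- Plot rendering is deliberately left out: matrices and row/column orders
  are exported for any plotting layer.
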