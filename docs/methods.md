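# Methods

flavorscape analyzes how recipe cultures differ in flavor, working from
three kinds of data: recipe corpora (one per portal/culture, each recipe a
bag of ingredient tokens plus an appreciation metric), a flavor taxonomy
(ingredient → flavor-compound sets, compound → flavor-profile words), and
the synthetic benchmark that stands in for scraped portal data. This note
records the models, the parameter choices, and the design decisions that
were genuinely open.

## Recipe representations

**Compound expansion.** A recipe's compound token list is the *multiset*
union of its mapped ingredients' compound sets: a compound carried by two
ingredients appears twice. The alternative (a set per recipe) discards
information that TF-IDF term frequencies are designed to use, so multiset
semantics were chosen. Ingredient tokens are lowercased, trimmed, and
internal whitespace collapsed; lookup is exact-match (no stemming or fuzzy
matching). Recipes whose every ingredient is unmapped are excluded from
compound-space analyses and counted; they remain in ingredient-space
analyses.

**TF-IDF.** tf is the raw token count; idf = ln((1+N)/(1+df)) + 1 with N
the number of recipes and df the token's document frequency; rows are
L2-normalized. This is the common smoothed-idf variant and is stated
bit-exactly so results are reproducible; it is computed through
scikit-learn's `TfidfVectorizer` with a pass-through analyzer.

**CBOW embeddings.** Each recipe's token list is sorted alphabetically and
used as one training sentence — the listing order of ingredients is
arbitrary, and sorting makes it canonical. The trainer is a compact
single-threaded numpy implementation of continuous bag-of-words with
negative sampling (unigram^0.75 noise, 5 negatives, linear learning-rate
decay from 0.025). Defaults: dimension 128, window = the whole sentence
(every token is context for every other in an order-free bag), min_count 2,
10 epochs. Ten epochs rather than a longer schedule because the trainer has
no frequent-word subsampling, and long training lets negative-sampling
repulsion between frequent co-occurring tokens dominate their similarity.
Recipe vectors are the arithmetic mean of the recipe's token vectors with
multiplicity; out-of-vocabulary tokens are skipped, and recipes with no
in-vocabulary token are excluded and reported.

## Classification tasks

The **origin task** is 3-class: predict a recipe's portal. The
**preference task** is binary per portal: recipes are ranked by
appreciation (ties broken by recipe id), the top and bottom 10% deciles
form the appreciated / less-appreciated groups, and a classifier separates
them. Only ranks are used, so each portal's metric scale (ratings,
bookmark counts, favorites) is irrelevant.

Three classifier families are provided: Naive Bayes (multinomial on
non-negative TF-IDF, Gaussian on signed embeddings), logistic regression,
and random forest. LOG and RF hyperparameters come from seeded 5-fold
randomized search on the training split (LOG C log-uniform 1e-3..1e3; RF
trees 100..500, depth {None, 10, 20, 40}, min leaf {1, 2, 5}). Because it
is ambiguous whether headline accuracies of this kind of study are
cross-validated or held out, reports carry both: accuracy on a seeded
stratified 80/20 held-out split, and the training-split 5-fold CV accuracy.
`search_iters=0` skips the search (useful for null-baseline runs where
labels carry no signal).

**Transfer.** The best preference model of a source portal (highest
held-out accuracy; ties prefer the simpler model) is applied frozen to a
target portal's extreme deciles. Target recipes are projected into the
source vocabulary by the source's fitted TF-IDF transform — unseen tokens
drop out, which is the only construction under which a frozen linear model
applies — and the vocabulary-overlap fraction is reported alongside the
accuracy. Zero overlap is an error, not an accuracy.

## Ingredient complement networks

Co-occurrence is counted at recipe level (presence, not multiplicity).
For an ingredient pair, PMI = ln[p(a,b)/(p(a)p(b))] and NPMI = PMI/h with
h = −ln p(a,b), bounded in [−1, 1]. Natural logarithms throughout (NPMI is
base-invariant; logged PMI values are base e). A pair that never co-occurs
maps to the −1 endpoint in pairwise queries; such pairs are simply never
edges. A pair present in every recipe maps to +1 (h = 0 limit).

Network thresholds are strict: nodes need occurrence > 10, edges need
joint co-occurrence > 5 and NPMI > 0.10. The 0.10 default mirrors a median
NPMI calibration; `min_npmi="median"` recomputes it per corpus. Nodes
passing the occurrence threshold but gaining no edge are dropped from the
graph and listed separately.

Nodes are embedded by second-order biased random walks (return parameter
p = 2 discourages immediate backtracking, in-out parameter q = 0.25
encourages exploration; 10 walks of length 80 per node; transition weights
are NPMI edge weights times the p/q bias) fed to the same CBOW trainer
(dimension 128, window 10, 5 epochs, min_count 1). Recipe vectors are means
of in-network ingredient node vectors; recipes with no in-network
ingredient are excluded and reported. K-means with k = 2 (n_init 10, fixed
seed) splits recipes into two clusters, labeled by the anchor rule: the
cluster whose recipes carry the sugar anchor at higher frequency relative
to the salt anchor is "sweet", the other "savory" (anchors configurable;
clusters stay unlabeled with a warning when both anchors are absent).
Finally the savory/sweet proportions of the appreciated and
less-appreciated groups are tabulated; each row sums to 1.

Networks are built per portal on the union of that portal's two extreme
deciles (the grouping is configurable), since the preference comparison is
defined on those groups.

## Flavor-profile clusters

Compounds occurring strictly more than 3 times in the collection and
carrying at least one profile word become rows of a Boolean compound ×
profile-word matrix (rows and columns sorted for determinism). The profile
matrix is built on the pooled collections so one compound clustering
underlies every portal's ratio table. K-means is scanned over k = 1..9;
the chosen k maximizes the second forward difference of the inertia curve
(discrete max curvature; ties toward smaller k; overridable). Identical
rows force k = 1.

Cluster naming uses prevalence P_pc = n_pc/N_c (fraction of cluster c's
compounds carrying profile p) and representativeness
R_pc = P_pc − mean_{c′≠c} P_pc′, ranked descending with lexicographic tie
breaks; the top 50 profiles name a cluster. Clusters are tagged
sweet/non-sweet by their summed representativeness of a sweet lexicon
(default {sweet, fruity, caramellic, sugary}) among the top-50 profiles:
clusters above the largest score gap are "sweet". If all scores coincide
everything is tagged non-sweet with a warning.

Distinctive ingredients of the two appreciation groups are ranked by
smoothed weighted log odds,
score(i) = ln[((n_A+1)/(total_A+1)) / ((n_L+1)/(total_L+1))], where n is
the ingredient's token count in a group and total is that group's total
token count. Token counts (with multiplicity) are used because the
quantity of interest is ingredient frequency. The per-group denominator was
chosen over a pooled one: a total shared by both groups cancels in the
ratio and would make the term vacuous. The top-50 and bottom-50 scores mark
the two groups' distinctive ingredients.

Each group's distinctive ingredients are then pooled into a compound
multiset (each ingredient contributes its compound set once, unweighted),
restricted to the profile-matrix compounds, and split into sweet vs
non-sweet fractions; a corpus-wide baseline row counts every in-scope
compound once and therefore equals the tag-level cluster-size proportions.
All rows sum to 1.

## The synthetic benchmark

The generator produces the structure the analyses are designed to detect,
with ground truth written to a separate JSON never read by analysis code.

* **Portals and recipes.** Three portals, 2000 recipes each by default;
  recipe length uniform on 8–11 (the cross-culture range of typical recipe
  sizes). Each recipe draws a latent class (sweet with probability 0.5)
  and always contains its class anchor (sugar/salt) — mirroring the
  observation that savory recipes feature salt and sweet ones sugar, and
  making cluster labeling testable. Companion slots draw from the portal's
  disjoint signature pool with probability 0.6, otherwise from
  class-conditional shared pools (crossing class with probability 0.1).
* **Appreciation.** Standard Gaussian noise plus a per-portal bias times
  the sweet indicator, min-max rescaled to a portal-specific metric range
  (ratings-like, bookmarks-like, favorites-like). Defaults (0, −0.6, +0.6):
  one neutral portal, one savory-favoring, one sweet-favoring. Rank-based
  decile selection makes the scale irrelevant; the noise family is not
  meant to mimic real portals' skewed metric distributions.
* **Taxonomy.** Compounds are partitioned into four balanced planted
  clusters; one cluster's profile pool is themed bitter/odorless-like, the
  others carry the sweet lexicon words. Each profiled compound draws 2–8
  words, mostly (95%) from its own pool, with word usage Zipf-weighted
  (exponent 1.5) inside each pool — a few dominant theme words describe
  most of a cluster, as in real flavor-profile vocabularies. Balanced
  cluster sizes are the standard planted-partition benchmark; the
  max-curvature elbow rule is structurally biased toward the first split
  when one cluster dominates, so strongly unbalanced splits (e.g. 45/55)
  are exercised through dedicated fixtures rather than the default.
  Sweet-anchored ingredients map predominantly (90%) to sweet-cluster
  compounds, savory-anchored ones to the non-sweet cluster. Signature
  ingredients carry compound sets from a menu of 12 flavor archetypes that
  is *identical across portals*: the j-th signature ingredient of every
  portal has the same compound family. Compounds are thereby fully shared
  across cultures — the origin signal lives in ingredient space (~perfect
  at this scale) and vanishes in compound space (~chance). Real data sit
  between these regimes because cultural fingerprints are only partially
  shared; at desk-scale n any fixed private compound signal is fully
  learned by a linear model, so the two honest regimes are the endpoints,
  and the fully-shared one expresses the phenomenon under study.
* **Determinism.** One RNG stream per portal is derived from the master
  seed (adding a portal does not perturb the others); a fixed seed yields
  byte-identical outputs. Every coverage guarantee (each compound
  referenced by ≥ 1 ingredient, each profile word used ≥ 1 time) is
  enforced by round-robin dealing before random fill, so configured sizes —
  including the published catalogue scale of 936 ingredients, 2254
  compounds, and a 927×510 profile matrix — are hit exactly, not just in
  expectation.

**What passing tests do and do not show.** The benchmark demonstrates that
each stage recovers what it is designed to recover under its own model
assumptions: planted signatures, a latent binary taste class with anchor
ingredients, planted compound clusters with heavy-tailed profile usage.
Real portal data add ingredient synonymy and translation noise, skewed
popularity metrics, non-binary taste structure, and partially shared
cultural fingerprints — none of which the generator emulates, so synthetic
accuracies should not be read as predictions of real-data accuracies.

## Numerical and operational choices

* All stochastic stages are seeded; k-means uses n_init = 10; CBOW training
  is single-threaded by construction. Reports are byte-identical across
  reruns of the same configuration.
* Ties: appreciation ranking falls back to recipe-id order (with a
  warning when all values coincide); representativeness and log-odds
  rankings break ties lexicographically; the elbow prefers smaller k.
* Degenerate inputs: empty networks are returned with a warning rather
  than an error; a profile matrix of identical rows forces k = 1; empty
  appreciation groups and empty compound pools are errors.
* Pipeline defaults favor speed over completeness: the algorithm grid is
  (NB, LOG) — RF is available but its randomized search dominates runtime —
  and the acceptance script runs the benchmark at 3×2000 recipes, which is
  large enough for all planted signals to be detected with wide margins.

## Known limitations

* The taste categorization is binary (savory/non-sweet vs sweet); sour,
  bitter, and umami are out of scope.
* Exact-match ingredient lookup means real-world synonym/translation
  variation must be resolved upstream of the taxonomy file.
* The CBOW trainer is desk-scale: it favors reproducibility over
  throughput and has no frequent-word subsampling or hierarchical softmax.
* The elbow rule is the discrete max-curvature heuristic; like all elbow
  heuristics it can be misled by strongly unequal cluster sizes, in which
  case `force_k` overrides it.
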