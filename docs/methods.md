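# Methods

## Problem and labels

Each subject carries three physical attributes — age (years), weight (kg),
height (m) — and four tibial-rotation angles in degrees (RTER, RTIR, LTER,
LTIR), each in [0, 90]. Two total, deterministic rules label a subject:

* **Rotation type.** Type 1 for angles in [0, 20], Type 2 in (20, 65],
  Type 3 in (65, 90]; Types 1 and 3 are pathological. The three half-open
  intervals partition [0, 90], so classification is total and monotone in
  the angle. The boundary convention (20° → Type 1, 65° → Type 2) follows
  the interval headers of the source tables; the surrounding prose is
  ambiguous at exactly 65°.
* **Physical cluster.** Cluster 1 iff age > 30; otherwise Cluster 2 iff
  weight ≤ 60 kg, else Cluster 3. The published threshold table also lists
  height (≤ 1.70 m vs > 1.70 m), but its rules are silent on discordant
  weight/height combinations; since the study stratified "by age and
  weight", the rule here uses weight alone below the age cut. Height remains
  in the data model and in the clustering features. Heights above 3 m are
  rejected with a message pointing at centimetre inputs.

## Synthetic cohort generator

The study's raw 484-subject table is not available; only its summary tables
are. The generator emulates exactly the categorical structure those tables
pin down and nothing more:

* **table_exact mode** takes per-rotation 3×3 type-by-cluster count panels
  (default: the published real panels, cluster sizes 52/249/183). Each
  subject's cluster comes from the shared column sums; within a cluster,
  type labels per rotation are shuffled multisets matching the panel column,
  so relabelling and tabulating the output returns the input panels
  *exactly*, for any feasible panel set. Panels that disagree on column sums
  or totals are rejected. Rotations without a panel get Type 2 angles.
* **parametric mode** draws cluster and per-rotation type memberships
  i.i.d. with given proportions (defaults: the study's observed
  frequencies).

Attributes and angles are drawn uniformly within the defining range of the
assigned cell: age U(31, 60] / U(18, 30], weight U(45, 60] / U(61, 100]
(Cluster 1: U(45, 100]), height U(1.50, 1.70] / U(1.71, 1.95] (Cluster 1:
U(1.50, 1.95]), angles uniform within the type interval (open on the left
for Types 2–3). Uniform-within-cell is the least-assumption sampler
consistent with the published thresholds; the study reports no attribute
distributions or correlations, so the generator makes no attempt at them.
Consequently, passing tests demonstrate correctness of the *pipeline
arithmetic* on cohorts with the study's categorical structure — not that
the clustering engines would reach the study's exact cluster outputs on the
real, unpublished attribute values.

One `numpy` `default_rng(seed)` stream drives all draws; identical seeds
give byte-identical cohorts (the CSV writer uses `%.17g` and the reader
round-trip float parsing to keep this exact on disk).

`well_separated_blobs` provides the engines' ground-truth fixture:
isotropic Gaussian clusters of spread `noise_sd` around centers spaced
`separation` per coordinate, with labels and centers returned.

## Clustering engines

Both engines minimise the within-cluster sum of squared Euclidean
distances, D = Σᵢ minⱼ ‖xᵢ − Cⱼ‖². (The source states the objective as an
unconditioned double sum over points and centers, which is
assignment-independent and cannot drive clustering; the standard
nearest-center reading is implemented.) Features are z-scored before
fitting — raw height (~0.2 spread in metres) would be numerically invisible
next to weight in kilograms — and the scaling record maps fitted centers
back to original units.

**K-Means** (`KMeansClusterer`): Lloyd's alternation of nearest-center
assignment (ties to the lowest center index) and centroid update, run to an
exact assignment fixed point (`tol=0`) or `max_iter=300`. Initial centers
are K distinct data points drawn uniformly without replacement. A cluster
that loses all members is re-seeded at the point farthest from its nearest
center. Because a single Lloyd run only finds a local optimum, the
estimator restarts `n_init=10` times from one seeded stream and keeps the
lowest-objective run; on an 8-point test instance only 6 of the 28 possible
point-pair initialisations reach the enumerated global optimum, so
restarting is load-bearing, not cosmetic. The per-iteration objective trace
is recorded and is non-increasing.

**Genetic algorithm** (`GeneticClusterer`): real-coded chromosomes of
n = K·p genes (K centers concatenated), fitness = D (minimised). Per
generation: truncation selection of the `n_parents` = 20 best; pairwise
crossover with rate 0.9 swapping a contiguous run of whole center blocks
(children are always valid center sets; a single-gene swap is the p = 1
special case); per-gene Gaussian mutation with rate 0.05 and step
sd = 0.05 × the gene's search-bound width, clipped to bounds (the
per-feature data range, widened by a machine-epsilon margin with a warning
if degenerate); elitism copies the 2 best members unchanged, making the
best-so-far fitness monotone non-increasing. Population 50, 200
generations. The source prescribes the operator *kinds* but no numeric
hyperparameters; these defaults are this package's declared choices, all
overridable. Final labels come from nearest-evolved-center assignment; a
center attracting no points is penalised implicitly by the objective — no
repair operator. One seeded generator drives selection order, crossover and
mutation, so runs are fully reproducible.

## Evaluation

Per rotation, a 3×3 type-by-cluster contingency table is built (marginals
always recomputed from cells — the published marginals contain a typo, a
row total printed as 24 whose cells sum to 54). Row-wise percentages are
100·count/row-total, rounded **half-up** to 2 decimals; zero-total rows are
undefined and render as "-", as do zero-count cells under the published
convention. The accuracy rate of a predicted against a real percentage is
100·min/max of the two *rounded* percentages (again half-up to 2 dp);
undefined when both are zero, 0.00 when exactly one is. This reproduces
every worked value in the source's results narrative (74.98, 84.79, 81.58,
81.36, 98.67, 90.79, 66.12, 99.38). Method labels are aligned to the
rule-based clusters by exhaustive search over the 3! permutations,
maximising agreement with lexicographic tie-break.

Known inconsistencies in the source tables, reported rather than forced:
four real-percentage cells differ by exactly 0.01 from their own counts
(LTER Types 1–3 Cluster 3, LTIR Type 2 Cluster 3); one published K-Means
percentage (RTIR Type 2 Cluster 2, 62.18 vs 62.17 from its counts) — the
published percentage is taken as the arithmetic's input, as the source
itself does; one accuracy cell evidently computed from raw counts
(RTER Type 3 Cluster 1 KM, 50.00 vs 49.93); two cells printed "-" where one
operand is zero; and a narrative "8.49%" that no formula consistent with
the rest reproduces. Tests assert exact agreement everywhere else and flag
these cells explicitly.

## Problem sizes and numerics

The test suite exercises the engines on blob fixtures of 150–180 points in
2-D and the 484-subject synthetic cohort, sizes at which every property
(global-optimum agreement by enumeration on N ≤ 8, reference-implementation
agreement at 1e-6 relative, center recovery within 3·noise_sd, GA within
5% of the K-Means objective) is checked in seconds. Enumeration oracles cap
at k^N ≈ 6 × 10³ assignments. All randomness flows through explicit integer
seeds; there is no global RNG state.

## Limitations

* The real cohort's attribute distributions and correlations are unknown;
  synthetic results quantify pipeline behaviour, not clinical performance.
* The accuracy-rate statistic compares marginal compositions, not per-subject
  agreement; a method can score well per cell while misplacing individuals.
* K = 3 is fixed by the study design; no model selection is offered.
* No significance testing of GA-vs-KM differences is performed.
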