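# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `proxikit`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Quantification model

Intensities are non-negative, finite and linear-scale; 0 encodes "not
quantified" and is never imputed. Two normalization scopes exist:

- **per_sample** — each sample column divided by its total, the usual
  total-intensity normalization of label-free data;
- **per_protein_across_conditions** — each peptide's (or protein's) values
  across condition groups divided by their sum, the targeted-PRM convention
  that yields relative shares per condition.

When heavy stable-isotope standards are present, endogenous peptide areas
are divided by the *mean* heavy-standard area of their (donor, condition)
group before sum-normalization: the standard corrects per-run load first,
then sum-normalization puts conditions on a comparable relative scale. The
order normalize → aggregate is fixed and explicit: peptides are
sum-normalized first and then averaged (unweighted arithmetic mean) to one
signal per (protein, donor, condition). Proteins are filtered by
unique-peptide support (≥2 for discovery-style matrices, ≥3 for stricter
tissue analyses — both are just `min_unique` values) and, for targeted
analyses, by complete quantification across all required (donor, condition)
cells.

## Differential abundance

The omnibus test runs per protein across condition groups:

- **ANOVA** on log2 intensities (variance stabilization for multiplicative
  intensity data);
- **Kruskal–Wallis** on ranks (identical on raw or log scale);
- **auto** uses Shapiro–Wilk per group (n ≥ 3; constant groups cannot
  reject) and switches to Kruskal–Wallis when any group rejects at 0.05.

Zeros are excluded per protein; a protein left without two groups of ≥2
values, or constant across all samples, is `degenerate` with p = 1.
Batch adjustment, when enabled, subtracts per-batch means on the log2 scale
(residualization) before testing — the simplest adjustment consistent with
"batch variance accounted for", and exactly testable.

Q-values are Benjamini–Hochberg step-up adjusted p-values (deterministic
and assumption-light; a Storey-type π₀ estimator would be a strict
extension, not a default). Omnibus p drives the q-values and the enrichment
call; direction comes from linear-scale fold changes of condition means
versus a reference (0/0 flagged `undefined`, x/0 flagged `infinite`, never
raised). The enrichment rule is q ≤ q_max AND fold change > fc_min in at
least one listed comparison.

## Pathway over-representation and crosstalk

The hypergeometric upper tail P(X ≥ k) scores over-representation;
depletion (the lower tail) is exposed behind `tail="lower"` but not used by
the pipeline, since enrichment is the quantity consumed downstream. The
default universe is the pathway-collection gene set intersected with the
detected proteome — the standard over-representation background that avoids
inflation from genes that could never be detected; it is a parameter, not a
constant. Significance is gated at p < 0.05 with the BH q reported
alongside (q_report = 0.15 by default).

The crosstalk graph uses Jaccard indices of *detected* member sets, so two
large pathways sharing only undetected genes are not linked. Edges below
j_min = 0.1 are discarded; modules are computed on this thresholded graph
(the graph one would visualize) by deterministic greedy modularity
agglomeration — chosen over stochastic optimizers for reproducibility.
Isolated nodes form singleton modules; module ids are ordered by decreasing
size, ties broken by lexicographically smallest member.

## Proximity statistic

d_c(S,T) is the mean over sources of the BFS distance to the nearest
target. Sources unable to reach any target are excluded from the mean and
reported, keeping d_c finite and the exclusion auditable (an alternative —
assigning an arbitrary large distance — would make the value depend on that
constant). d_c = 0 exactly when S ⊆ T.

The null preserves the degree profile by node-set resampling on the fixed
topology (not edge rewiring): nodes are binned by ⌊log2(degree)⌋, adjacent
bins merged upward until each holds ≥ `min_bin_size` (default 10) nodes,
and each member of the randomized set is replaced by a draw without
replacement from its bin. Observed distances therefore live on the true
network, and 200+ draws are cheap. Bin parameters are configuration, not
constants. By default only S is randomized (T is the fixed reference gene
set); `randomize` exposes `S`, `T` and `both`. When only S is randomized
the distance-to-target field is computed once and each draw reduces to an
average lookup.

The empirical p-value is (r+1)/(n+1) with r the count of null d_c ≤
observed — the pseudocount avoids p = 0 at finite n and makes the test
slightly conservative (the smallest attainable p at n = 200 is 1/201).
The test is one-sided toward proximity. The z-score
(observed − null mean)/null sd is reported descriptively and flagged
undefined when the null has zero spread.

## Synthetic-data design

The generators define the study conditions used throughout the tests:

- **Network**: preferential attachment (500 nodes, 3 edges per new node in
  the default pipeline) — connected, simple, heavy-tailed. The heavy tail
  is the one property the PPI stand-in must reproduce, because it is what
  makes degree-preserving nulls non-trivial. It does not reproduce the
  clustering, community structure or degree correlations of curated
  interactomes.
- **Abundance**: log2 intensity = baseline N(20, 2) + condition effect
  (effect_log2fc for planted proteins in the enriched condition, default
  the last label) + donor intercept N(0, donor_sd) + batch offset
  N(0, batch_sd) shared by a batch's donors + noise N(0, noise_sd);
  intensities are 2^log2. Fold changes are exact in the noiseless limit,
  and exact for condition-mean ratios even with donor intercepts, because
  every donor contributes to every condition. Default design: 3 conditions
  × 9 donors, 10% planted, effect 1.5 log2, noise sd 0.3, batch sd 0.1.
  Unique-peptide counts are uniform on {1..10}.
- **donor_sd defaults to 0.** The donor intercept is modeled (it is a
  parameter) but the default is zero: with shared donors across conditions,
  intercept variance cancels from between-group means while inflating
  within-group variance, making the unpaired omnibus tests conservative.
  The package's default test is unpaired (as is standard for these omnibus
  comparisons), so the default generator keeps the two consistent; analyses
  of strongly donor-structured data should use a paired/mixed model, which
  is out of scope here.
- **Pathways**: sizes uniform in [size_min, size_max]; consecutive pairs
  share ⌈overlap_fraction × size_min⌉ members so crosstalk edges exist by
  design; accidental extra overlap is possible and the designed shares are
  recorded in the truth object.
- **Planted proximity**: targets drawn uniformly; sources drawn from the
  nodes within `radius` edges of the target set (a subset of the targets
  when radius = 0). Construction guarantees d_c ≤ radius.

The intensity model is a modeling decision: real label-free data also show
intensity-dependent variance, missingness correlated with abundance, and
shared-peptide ambiguity, none of which are simulated. Passing tests
demonstrate the correctness and calibration of the *computations* under a
clean log-normal design, not robustness to those real-data pathologies.

## Pipeline and problem sizes

The default pipeline simulates a coherent study: the planted proximity
source set doubles as a planted pathway (`PW_PLANTED`) and its members are
a subset of the planted differentially-enriched proteins, so recovery can
be scored at every stage. Sample-total normalization induces a real
compositional side effect — non-planted proteins are slightly deflated in
the enriched condition — which is realistic and visible in the enriched-set
size; the fold-change gate keeps direction interpretable.

Statistical checks run at sizes chosen to estimate rates with useful
precision while staying desk-scale: 100 random graphs for the BFS oracle,
all hypergeometric configurations to N = 12 for the enumeration oracle,
1000 vectors for the BH oracle, 500 trials × 200 randomizations for null
calibration, 50 runs for planted recovery, 20 replicates of 1000 proteins
for FDR/power, and 2000 proteins for type-I calibration. All randomness is
seeded; identical seeds reproduce every artifact byte-for-byte (floats are
written with 17 significant digits, manifests contain no timestamps and
only run-relative paths).

## Known limitations

- No imputation and no mixed-effects modeling of the paired donor design.
- Post-hoc pairwise tests (Bonferroni/Dunn) are not computed; direction is
  taken from fold changes.
- The crosstalk graph and modules depend on the detected-set definition;
  with sparse detection, pathway nodes can vanish (reported as warnings).
- Proximity variants beyond closest distance (separation s_AB, shortest
  path kernels) are out of scope.
- The degree-binned null matches marginal degree only, not joint placement
  (e.g. co-membership in dense regions).
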