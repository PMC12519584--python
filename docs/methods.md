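# Methods

## Scope and data model

The pipeline analyses longitudinal microbial community tables: taxa × sample
abundances (counts or relative), a rooted phylogeny with branch lengths whose
tips name the taxa, and per-sample metadata (subject, timepoint label, hours
since the perturbation, optional reconstruction stage). The canonical
schedule is a pre-scaling baseline (coded `hours = −1`) followed by 0, 1, 4,
7 h, 1, 3, 7, 14 d, 1, 3 months and 1 year (hours 0, 1, 4, 7, 24, 72, 168,
336, 720, 2160, 8760). Post-perturbation timepoints partition into
reconstruction stages: **early** ≤ 7 h, **middle** ≤ 168 h (1 d, 3 d, 1 w),
**late** ≥ 336 h. The partition is available both as this fixed rule and as
a data-driven alternative (contiguity-constrained average-linkage clustering
of timepoint centroid distances into three time-ordered groups).

Alignment policy: taxa absent from the tree are dropped with a warning
(phylogenetic metrics are undefined without branch placement); an error is
raised when more than 10% (configurable) of taxa would be lost. Tables whose
columns sum to 1 ± 1e−6 are auto-flagged as relative.

## Recovery-trajectory statistics

* **Shannon diversity** in log base 2 (bits) by default, configurable.
* **Weighted UniFrac**: branch-length-weighted L1 distance between the
  descendant-mass profiles of two relative-abundance communities. The
  normalized form (default) divides by Σ_j d_j (a_j + b_j) with d_j the
  root-to-tip distance, bounding values to [0, 1]. Implemented by a
  postorder branch decomposition (branch lengths + tip membership matrix),
  which also vectorizes the all-pairs distance matrix.
* **PCoA**: Gower double-centering of −½D², symmetric eigendecomposition,
  axes from positive eigenvalues only (negative eigenvalues are reported,
  never embedded; proportions explained are over the positive spectrum).
* **Baseline trajectory**: for each post-perturbation timepoint, the
  within-subject distance to that subject's own baseline sample, averaged
  over subjects with a Student-t 95% CI. Subjects without a baseline sample
  are excluded with a warning; a single-distance timepoint is reported with
  a degenerate (zero-width) CI.

## Community-assembly inference

**βMNTD** is the abundance-weighted mean nearest-taxon phylogenetic distance
between two communities; shared taxa contribute zero to their own term, so
identical communities score 0. **βNTI** is the standardized effect size
(observed − null mean)/null SD over a null that randomizes taxon positions
on the phylogeny (tip shuffle) with abundances fixed. Each community in a
pair receives an **independent** permutation per iteration. The more common
convention shuffles tips once per iteration for all communities; under that
shared shuffle a pair of identical communities has βMNTD 0 in every null
draw and its SES is undefined, whereas the independent shuffle scores such
pairs as strongly under selection — the behaviour we consider correct for a
statistic meant to flag communities more phylogenetically coherent than
chance. For non-identical communities the two conventions agree closely.
Pairs with zero null SD return NaN (flagged undefined), never ±∞. Default
999 null draws (floor 99); βNTI is exactly invariant to taxon row order
(taxa are canonicalized internally) and to uniform branch-length scaling.

**Raup–Crick (Bray–Curtis form)**: null communities preserve each sample's
richness and total abundance; species enter with probability ∝ occupancy
frequency across the table, then remaining individuals are assigned
multinomially ∝ mean relative abundance; `rc = 2((n_less + ½n_ties)/n_null −
½) ∈ [−1, 1]`. Relative tables are scaled to 10⁴ counts with presence
preserved. Known property: on high-occupancy tables (every taxon in every
sample, e.g. deeply sequenced within-cohort pairs) the null collapses to
near-identical mean communities, so ordinary between-subject variation
scores rc ≈ +1; process proportions on such data should be read with that
in mind.

**Partition** (per pair): βNTI < −2 homogeneous selection; > +2 variable
selection; otherwise RC > 0.95 dispersal limitation, RC < −0.95 homogenizing
dispersal, else undominated. Both thresholds are configuration-exposed.
Pairs are all within-timepoint subject pairs, giving per-timepoint process
proportions that sum to 1.

## Co-abundance modules

Pearson correlation (Spearman optional) across samples → unsigned
soft-threshold adjacency |r|^β with β = 12 (signed variant available) →
topological overlap TOM → average-linkage clustering of 1 − TOM → static
tree cut. The split-sensitivity setting maps to a cut-height ladder
{0.95, 0.90, 0.85, 0.80} for depths 1–4 — a reproducible stand-in for
dynamic tree cutting; deeper cuts are stricter, shedding noisy members to
the unassigned (grey) group. Clusters below the minimum size (default 7)
are unassigned; modules are relabeled by decreasing size and named with the
standard ordered color palette, so color names identify size rank, not any
particular membership. Constant taxa get zero correlation rather than NaN.

Module representatives are the first principal component of the
standardized member × sample matrix, sign-oriented to track the members'
mean profile, unit variance (an eigentaxon). Module–time association is the
Pearson correlation of the representative with each timepoint's indicator
vector; a module's stage is the stage containing its most positively
associated timepoint (p < 0.05 flagged).

## Driver inference (delta correlation)

For transition s → s+1: per subject, stage means are arithmetic means of
relative abundances over the subject's samples in the stage; the target
variable is the per-subject **change** Δ = mean(s+1) − mean(s) (the raw
later-stage abundance is a supported alternative); the statistic is
Spearman's ρ across subjects between source stage-s abundance and target Δ.
P-values use the t approximation, switching to the exact permutation null
for ≤ 9 subjects; constant vectors are flagged undefined and excluded.
Edges are retained when ρ > 0 and the BH-adjusted q (across all candidate
pairs of the transition) is < α = 0.05 — the positivity filter also
discards the spurious negative couplings that compositional renormalization
induces. Candidate pairs default to earlier-stage module members × later-
stage module members; adjacent transitions only. The pairing unit is the
subject: with ~30 subjects it is the only replicated unit, and it makes the
test a paired design. A generic paired-table cross-correlation (rows of X ×
rows of Y over shared units) serves module-by-function association.

## Synthetic-data generator

The generator plants every structure the pipeline infers:

* **Phylogeny**: pure-birth (Yule) tree grown to n tips, extended by the
  waiting time to the next speciation so the youngest pair has positive
  branch lengths; ultrametric; tips `taxon_1..n`.
* **Baseline community**: lognormal taxon weights (σ = 1) shared across
  subjects; early-module members are scaled down (default ×0.3) because
  early colonizers after cleaning are low-abundance environmental
  transients.
* **Stage curves**: piecewise-linear tents on the log10(1+hours) axis.
  Early modules bloom over 0–4–24 h, middle over 7–72–336 h; late modules
  *dip* over 0–72–2160 h (nadir at day 3 — the planted maximal disruption)
  and return exactly to baseline from 3 months on. Multipliers are
  1 ± amplitude·tent; baseline samples are untouched.
* **Noise**: per-subject and per-sample lognormal factors (sd `noise_sd`,
  default 0.3). A fraction `module_cor` (default 0.95) of the noise
  *variance* is shared within each module, so members covary beyond their
  common stage curve — that covariance is what makes them a detectable
  co-abundance module; at the default, observed member correlations are
  ~0.9, matching what soft-threshold networks at β = 12 can resolve.
* **Drivers**: a driver (source, target, s→s+1, γ) adds γ × (subject's
  source latent stage-s mean, pre-driver) to the target's latent abundance
  at every stage-s+1 timepoint, before renormalization. With γ = 0 no edge
  is recorded in the ground truth.
* **Observation**: multinomial counts at fixed depth (default 10⁴), so
  columns sum exactly to the depth and compositionality is enforced.
* **Assembly pair sets**: `selection` draws every community's members from
  the single smallest clade holding ≥ richness tips (a shared environmental
  filter); `neutral` draws members uniformly; lognormal abundances,
  normalized.
* Seeding: one seed spawns independent substreams (baseline, per-subject,
  observation), so runs are bit-reproducible.

The **driver benchmark** (`driver_benchmark_config`) builds 10 early sources
× 10 middle targets (100 candidate pairs) and plants 5 edges between
abundance-rank-matched members, chosen from a driverless reference run: a
driver whose source sits below the sequencing-depth counting-noise floor is
unrecoverable by any method, so the benchmark plants effects only where the
design permits detection. It sets `module_cor = 0` so that recovered edges
reflect the planted drivers rather than shared module fluctuation.

What the generator does **not** emulate: read-level sequence artifacts
(chimeras, OTU clustering), within-mouth spatial structure, taxon-specific
interaction networks beyond the planted linear driver effects, and
phylogenetic signal in the recovery dynamics (module membership is
independent of the tree). Passing tests therefore demonstrate that the
inference machinery recovers planted structure under compositional counting
noise — not that real subgingival data satisfy these models.

## Numerical choices and edge cases

Distance matrices are symmetrized against floating-point noise and have
exact zero diagonals. PCoA eigenvalues below a relative 1e−12 tolerance
count as zero; requesting more axes than positive eigenvalues truncates
with a warning. All-zero samples raise a degenerate-sample error naming the
sample. βNTI with zero null SD, constant correlation vectors, and
constant-member modules are flagged (NaN / degenerate sets) rather than
silently dropped. Module relabeling breaks size ties by first member name,
making detection order-independent up to label names. Problem sizes in the
shipped analysis scripts (6-subject sub-cohort at 99 null draws for the
per-timepoint assembly partition; 199 draws for the planted-regime checks)
were chosen to keep the narrative pipeline interactive while leaving the
statistics stable.

## Known limitations

The static cut-height ladder is an approximation of dynamic tree cutting:
at the deepest setting it trims noisy members to grey (cohort ARI ~0.7
against planted membership at default noise, vs ~0.99 one level up).
Delta correlation is a lagged rank association, not causal identification;
renormalization couples taxa, and only the positivity filter plus FDR
control keep that coupling out of the edge set. The Raup–Crick occupancy
null is uninformative on saturated-occupancy tables (above). Exact Spearman
p-values are computed only for ≤ 9 subjects (9! permutations); beyond that
the t approximation is standard and accurate.
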