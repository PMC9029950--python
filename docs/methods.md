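# Methods

This note documents the models and algorithms implemented in
`leukoflow`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical corner
cases.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scale transform

All clustering, calibration and phenotyping operate on a transformed
fluorescence scale.  The default is `arcsinh(x / c)` with cofactor
`c = 150`, the standard choice for 8-color digital cytometers: linear
through zero (so compensated negative values remain meaningful) and
logarithmic above a few hundred units.  A logicle (biexponential)
display scale is also provided, implemented by the usual
parameterization (T = data top, M = 4.5 decades, W = 0.5) and inverted
by monotone interpolation on a 4,096-point grid; `none` passes values
through.  Scatter and time channels are never transformed.  The
transform is strictly monotone per channel, so rank order — and hence
every median-based statistic — is preserved.

FCS support is FCS 3.0/3.1 read (float, double, and uniform-width
integer list-mode DATA, either byte order) and FCS 3.1 float32 write.
FCS 2.0 is rejected outright: its byte order and amplification keywords
are too ambiguous to parse by guesswork.  Compensation is assumed
pre-applied in the file; spillover keywords are not interpreted.

## Phase 1 — data validation

**Flow stability.**  Events are ordered by the time channel and cut into
windows of 1,000 events.  A window is flagged when its FSC-A mean
deviates from the robust center of all window means (median) by more
than `deviation_k = 4` times the robust spread (1.4826 × MAD).  The
robust pair matters: a genuine drift interval shifts both the plain mean
and the plain SD of window means, and can thereby mask itself; against
median/MAD a 10-SD clog interval is flagged while stationary Poisson
variation is not.  Flagged windows are excluded by default (a warn-only
flag exists); the count appears in the QC report.

**Doublets.**  A doublet's FSC-A (area) is roughly the sum of its
constituent cells while FSC-H (height) tracks the larger one, so
doublets fall below the singlet line in the FSC-A/FSC-H plane.  The line
is fitted by Theil–Sen regression of FSC-H on FSC-A over the central
5–95% FSC-A bulk (subsampled to 2,000 points — the estimator is
quadratic in pairs — which does not change the median slope
meaningfully).  The margin is `margin_k = 3` × 1.4826 × MAD of the
residuals; events more than the margin *below* the line are doublets,
and an event exactly on the boundary is a singlet.  A one-sided 3-robust-SD
margin flags ≈ 0.1% of true singlets, so "clean data passes untouched"
holds only approximately (≥ 98.5% retention is the tested property).

**Debris.**  A Gaussian mixture over standardized (FSC-A, SSC-A), with
the component count chosen by BIC up to 6, clusters the scatter plane;
the lowest-FSC-A cluster(s) are labeled debris while their median FSC-A
is below `debris_fsc_fraction = 0.25` of the median FSC-A of the
remaining (nucleated) events.  Populations differing only in SSC-A are
therefore never debris.  If the mixture fit fails, a fixed FSC-A
percentile threshold is used and a warning recorded.

The three stages run in a fixed order (stability → doublets → debris) so
each removed event has exactly one cause and the QC report conserves
counts: unstable + doublets + debris + retained = total.

## Phase 2 — density–phenotype coupled clustering

Two criteria jointly define a population: the event-density landscape
over all analysis channels (markers plus FSC-A/SSC-A, each robustly
z-scored), and the five-level phenotype (bright / positive / partial /
dim / negative) of every marker.  The algorithm has four deterministic
stages:

1. **Mode seeking.**  k-nearest-neighbour density (k = ⌈√n⌉ capped at
   100) with each event ascending to its nearest higher-density
   neighbour; ties break by event index, so the ascent is well founded
   and reproducible.  Graph roots are density modes; their basins
   deliberately over-segment.
2. **Phenotype split.**  A basin whose members disagree on some marker's
   level (2nd vs 98th percentile, wide enough to see a few-percent
   subpopulation) is examined on the worst such channel with a 1-D
   two-component Gaussian mixture.  The split is accepted only if the
   two-component fit beats a single Gaussian by > 10 BIC, both
   components hold ≥ 2% of the segment, and the means are separated
   beyond twice the narrower component SD — a single population
   straddling a level boundary fails these and stays whole.  This stage
   recovers small populations (e.g. NRBCs under a dominant CD45-dim
   blast cloud in a tube whose antibodies cannot separate them) that
   slide into a large neighbour's density basin.
3. **Merge.**  Adjacent segments (sharing kNN cross-edges) merge only
   when BOTH criteria agree they are one population: five-level
   signatures within `merge_levels_tolerance = 1` per marker, AND
   density continuity — the pair's events are projected onto the line
   joining the segment centroids, and the smoothed 1-D density between
   the two projected medians must stay above `continuity_ratio = 0.65`
   of the lower flanking peak.  The 1-D projection is the key numerical
   choice: raw kNN-density ratios compress toward 1 in 10 dimensions
   (making valley thresholds dimension-dependent), whereas slices of one
   population always project valley-free (ratio ≈ 0.9–1.0) and genuine
   population pairs project a deep valley (ratio ≤ 0.5) at any
   dimension.  One merge per pass, strongest adjacency first, until no
   admissible pair remains — so a density-continuous but
   phenotype-distinct pair stays split, and vice versa.
4. **Absorption.**  Populations below `min_fraction = 0.05` (the scale
   the method is tuned for; configurable down to 0.001, though
   rare-event performance is untested) are absorbed into the nearest
   larger cluster by summed signature rank distance, then MFI distance.
   Summed (not max) distance matters: it sends a sub-threshold monocyte
   cluster to the granulocytes rather than to a blast cluster that
   happens to share one strong marker.

**Five-level calibration.**  Per channel, the negative/dim boundary sits
at the "negative anchor": the 99th percentile of the lowest density
mode's basin.  The basin ends at the first *deep* valley (density under
half of both flanking prominent modes, with ≥ 2% of events to its
left) — sampling wiggles in an all-negative channel never qualify, so
such channels map everything to negative.  The anchor is capped at an
autofluorescence ceiling of 1.2 transformed units (≈ the top of an
unstained population on the arcsinh scale), which keeps a dominant dim
population from swallowing a small negative mode in its shoulder.  The
remaining cuts sit at 0.25 / 0.5 / 0.8 of the span between the anchor
and the 99.5th percentile, with a minimum span of 3 transformed units so
the levels are never narrower than single-population noise.  Boundary
values resolve to the higher level, so "partial" never silently
collapses into "dim".  All cut parameters are exposed.

## Phase 3 — cluster classification and cross-tube matching

Cluster features are the per-channel MFI (median), robust SD, and nine
deciles, plus the cluster fraction — deterministic and cheap.  The
default classifier is a transparent rulebook mirroring manual CD45/SSC
gating: CD45-dim plus an immaturity marker (CD34/CD117/CD10) ⇒ blast,
with lineage via CD19+CD10/CD79a (B), cCD3 or CD3+CD7/CD5 (T), MPO or
≥ 2 of CD13/CD33/CD117 (myeloid); CD45-bright low-SSC ⇒ lymphocyte
subsets; CD14/CD64 ⇒ monocyte; high SSC with myeloid markers ⇒
granulocyte; CD45-negative low-scatter without lineage evidence ⇒ NRBC.
Contradictory lineage markers yield `unclassified` rather than a guess.
A tube without myelomonocytic antibodies deliberately leaves
granulocytes/monocytes unclassified — CD45/SSC alone cannot separate
them in a blast-heavy marrow — and relies on cross-tube integration.

A bagged random forest (scikit-learn, bootstrap aggregating, out-of-bag
accuracy recorded, seed-deterministic, serializable) is available as a
trained alternative with a training harness over labelled synthetic
cohorts; confidence below 0.6 becomes `unclassified`.

**Cross-tube matching** anchors on the channels all tubes share (CD45,
FSC-A, SSC-A): cluster MFIs are robustly z-scored against each tube's
own event distribution, and the score is the per-channel-normalized
Euclidean distance plus 0.5 × |fraction difference|.  Best score wins;
above threshold 2.0 the cluster is unmatched.  Matching is many-to-one
(a population split in one tube may match a single cluster elsewhere).
Integration lets an unclassified cluster inherit a counterpart's
category when that counterpart's confidence is ≥ 0.8; a generic
`lymphocyte` may be refined to T/B/NK and `blast_unassigned` to a
lineage-assigned blast, since other tubes carry the deciding markers.
Disagreeing counterparts leave the cluster as it was, with a warning.

## Phase 4 — diagnosis

Blast clusters of one lineage merge when their summed signature rank
distance is within tolerance (default 4); distinct lineages never merge
and produce an ambiguity warning.  The abnormal fraction is the merged
blast share of QC-retained nucleated events (the denominator choice:
these are the cells a manual examiner would gate over), reported to
0.1%; the case value is the median across tubes, since every tube
re-measures the same marrow and the median resists one tube whose panel
cannot separate blasts from a neighbouring compartment.

The decision layer uses the conventional ≥ 20% blast threshold: below
threshold with no reportable blast cluster ⇒ `Normal`; at or above with
an unambiguous lineage ⇒ AML / B_ALL / T_ALL; MPO-negative myeloid
patterns cross-expressing lymphoid antigens (CD7/CD56/CD2), dim-only
lineage-specific markers, conflicting lineages, blasts below threshold,
or a fraction within 5 points under threshold ⇒ `Abnormal_review`, which
always carries at least one explanatory warning.  Mixed-phenotype
patterns are always routed to review — the rulebook is a deliberately
simplified WHO-inspired layer, not a WHO implementation.  Normal
compartments are additionally checked against expected level ranges
(granulocytes CD13/CD33 ≥ partial, lymphocytes CD45 bright, monocytes
CD14/CD64 ≥ partial, …) and deviations reported as named warnings.

## Agreement statistics

Consistency is diagonal mass over n (total and per manual category).
Cohen's κ is unweighted by default, computed after embedding the table
into the square union of both raters' label sets with zero fill — the
convention that handles an AI-only "flag for review" column; a linearly
weighted variant sits behind a flag.  Bland–Altman uses the sample
(n−1) SD and 1.96 limits.  Pearson r and the paired t test come from
scipy.  Degenerate inputs (empty tables, all mass in one cell pair,
zero-variance differences) raise rather than return NaN.

Two published validation tables ship as raw-count CSVs; every statistic
over them is recomputed at run time, and a brute-force oracle (κ of the
table expanded into per-case rating pairs) checks the table-based κ to
1e-12 across all 25 antigen rows.

## Synthetic bone-marrow generator

Populations are multivariate Gaussian on the transformed scale
(log-normal-like on the linear scale the FCS files carry) with five
canonical level locations (negative 0.3, dim 1.6, partial 2.7, positive
4.0, bright 5.5; SD 0.35) and literature-shaped scatter (granulocytes
high SSC, monocytes large FSC intermediate SSC, NRBCs small and
SSC-low, blasts intermediate).  Normal marrow is granulocytes 50%,
T cells 15%, NRBCs 13%, monocytes 10%, B cells 7%, NK cells 5%.
Leukemic templates put blasts at a configurable fraction (default 0.5,
cohort draws uniform 0.3–0.7) with the normal compartments scaled down
proportionally; typical AML / B-ALL / T-ALL phenotypes are joined by two
hard review cases — MPO-negative myeloid blasts cross-expressing
CD7/CD56, and T-lymphoblasts with only dim cCD3 plus myeloid
cross-expression — mirroring the presentations that defeat simple
lineage rules in practice.

Artifacts have exact bookkeeping: ⌊doublet_frac·n⌋ doublets (pairing two
cells: areas and linear fluorescence add, FSC-H takes the larger
parent), ⌊debris_frac·n⌋ debris events (low scatter, autofluorescence
signal), and an optional FSC-A drift over a stated acquisition interval.
Cross-tube identity is simulated as a real aliquoted sample behaves:
each population's location is drawn once per case and only jittered per
tube, which is what makes backbone anchor matching meaningful.
Everything is reproducible event-for-event from the seed; the default
cohort mix echoes a published acute-leukemia caseload balance
(AML : B-ALL : T-ALL : non-leukemic = 138 : 53 : 9 : 94).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: spectral spillover residuals and
compensation error, baseline restoration artifacts, non-Gaussian
population shapes (maturation continua, activation smears), day-to-day
instrument drift in fluorescence (only scatter drift is modeled),
doublet coincidence correlated with acquisition rate, and real MFI
distributions of any particular instrument or antibody lot.  Recovery
rates on this generator are an upper bound on clinical performance, not
an estimate of it.

## Problem sizes and reproducibility

The test suite and acceptance script run desk-scale workloads chosen to
exercise every claim on one CPU: 2,000 events/tube × 4 tubes for
pipeline cases, a 100-case balanced cohort for end-to-end recovery,
20,000 events for QC artifact recall, 500 events for the
clustering-vs-mixture oracle.  Every random draw — simulation, forests,
t-SNE — flows from an explicit seed, and the full pipeline is
byte-reproducible under a fixed seed (hash-checked in the acceptance
layer).  The t-SNE embedding is scikit-learn's, seeded, with uniform
per-cluster downsampling to at most 20,000 events.

## Known limitations

Rare-event (< 0.1%, MRD-level) populations are outside the validated
operating range.  The rule-based classifier covers the bundled 4-tube
screening panel's markers; unusual panels need rulebook edits or the
forest path.  Cluster-level (not per-event) classification means a
cluster contaminated below the majority level is scored by its majority.
The HTML report is the primary render; PDF is delegated to the viewer's
print function.
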