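# Methods

This note documents the models, conventions and defaults behind
`modconn`, the choices made where the procedure admits more than one
reasonable reading, and what the synthetic tests do and do not establish
about real data.

## Functional connectivity construction

Edges are Pearson correlations between node time series, Fisher
z-transformed and, by default, z-scored across the subject's own
upper-triangle edge distribution before negative values are set to zero
(`rectify_on="standardized"`). The alternative order — rectify by the
sign of the raw correlation — is available as `rectify_on="raw"`;
when combined with standardization, any standardized value that remains
negative is floored at zero so the nonnegativity contract always holds.
Correlations are clipped to ±(1 − 1e−7) before `arctanh` so duplicated
series produce a large but finite weight. The per-subject scope of the
z-scoring (rather than per-edge across subjects) was chosen because it
needs no group information and keeps each subject's matrix
self-contained.

Proportional thresholding retains K = floor(S · N(N−1)/2) strongest
edges. Ties at the cut are broken by lexicographic node-pair order,
which makes results platform-independent and edge sets nested across
the grid. Retained weights are unchanged (the network stays weighted).
Connectedness is not enforced; a disconnected thresholded network is
logged as a warning. Note one consequence for matrices with few distinct
values (e.g. noiseless block matrices): below the within-module pair
count the tie-break, not the data, decides which edges survive.

## Consensus community template

The Louvain pass is `networkx.community.louvain_communities` (seeded,
weighted, resolution fixed at 1.0 by default and exposed in the config).
Consensus iterates: run Louvain `n_runs` times; build the agreement
matrix of co-assignment frequencies; zero entries ≤ τ = 0.2; re-cluster
the thresholded agreement matrix; repeat until every run returns the
identical partition. Testing "all runs identical" is exactly the binary
block-diagonal condition without floating-point comparisons. Nodes
isolated by the τ-threshold keep singleton communities.

Subject-level agreement matrices (one per subject, `n_runs` runs each)
are averaged over the pooled cohort — both groups, so the template does
not favor either — and the same consensus iteration applied to the
average yields the group template. Averaging was chosen because it is
symmetric in subjects and uses every run; the alternative (pooling run
label vectors directly) weights subjects identically and converges to
the same fixed points in practice.

Seeds follow a ladder: run r of subject s uses
`seed + s·10⁶ + r`, consensus iteration t adds `t·10⁴`, and the
group-level reruns start above the subject ladder, so no stream is
reused anywhere in a cohort run.

## Modularity and ASMI

Q is Newman's weighted modularity of the *fixed* template applied to
each subject at each sparsity; the AUC uses the composite trapezoid rule
on the 0.05–0.30 grid (step 0.01), so a constant curve c integrates to
0.25c. ASMI between two modules is the sum of connecting-edge weights
divided by the number of connecting edges, where "connecting edges"
means suprathreshold (nonzero) edges counted once per unordered node
pair; a pair with no connecting edge is reported as undefined rather
than zero, and excluded from the group test with a warning. The
permutation statistic is the group mean difference (equivalent to a
t-statistic under label permutation), two-tailed via absolute value,
with the +1 exceedance correction so p ≥ 1/(n_perm+1); BH-FDR is applied
across the module pairs (six pairs for four modules).

## Connector hubs

PC and WMD default to strength (weighted) connections; a binary mode is
provided. WMD uses the population (divide-by-n) standard deviation both
within modules and for the mean + SD hub cut — the convention must be
fixed for the cut to be reproducible, and the population form makes
within-module z-scores sum to exactly zero. The CH rule uses strict
inequalities (PC > 0.3 and WMD > mean + SD). The PC/WMD group comparison
averages ratios within subject first and applies a pooled-variance
t-test on the subject-level means: with ~30 subjects per group this
matches the reported scale of such comparisons, whereas pooling all hub
nodes across subjects would treat nodes as independent and grossly
overstate the evidence. Subjects without any CH are excluded with a
warning; a CH with WMD ≤ 0 cannot occur when the cut is positive but is
guarded against.

The CH frequency ranking pools both groups, sorts by count with ties
broken by node order, and keeps floor(0.25 · N) nodes — 22 of 90.

## Network-based statistics

The edge statistic is the group mean difference in the stated direction;
one analysis per direction, each at one-tailed α = 0.025. A single
seeded permutation sequence serves both the edge p-values and the
max-component null: each permutation's statistics are converted to edge
p-values by their rank among all permutations (the permutation itself
playing the role of the +1 term), thresholded at p < 0.005, and the
largest component's edge count recorded. Corrected p for an observed
component of size s is (1 + #{null max ≥ s})/(1 + n_perm), which is
monotone in s within a run.

## Topology and null models

Weighted clustering uses the Onnela geometric-mean form with weights
scaled by the network maximum (scale-invariant); weighted path lengths
use edge lengths 1/w; disconnected pairs are excluded from Lp with the
count logged. Local efficiency is Latora–Marchiori on the neighbor
subgraph, with disconnected neighbor pairs contributing zero.

Null networks preserve the binary degree sequence exactly via
Maslov–Sneppen double-edge swaps (10 × edge-count attempts), after which
the original weights are randomly permuted onto the rewired edges (the
procedure for weighted nulls is a modeling choice; degree-preserving
*weighted* rewiring has no canonical form). γ, λ and σ = γ/λ are ratios
against the null-ensemble means.

Nodal degree centrality is raw binary degree and is *not* normalized by
the nulls: rewiring preserves degree exactly, so the normalized value
would be identically 1. Nodal clustering and local efficiency are
likewise reported raw by default (null-normalized variants are available
by flag); their raw AUC magnitudes, like degree's forced mean AUC of
(N−1)(0.30²−0.05²)/2 ≈ 3.89 at N = 90, are the quantities comparable
across studies.

## Synthetic cohort generator

Subjects are draws from a block-structured multivariate normal: unit
variances; ρ_within on same-module pairs, ρ_between on cross-module
pairs; hub nodes get max(ρ_hub, ρ_between) on their cross-module pairs
and ρ_within + 0.10 inside their own module. The within-module hub boost
reflects what a connector hub is empirically — a high-strength node
overall — and is required for planted hubs to satisfy the joint
PC-and-WMD selection rule; without it a hub's within-module degree is
average and hub selection is driven by noise. Temporal structure is a
stationary AR(1) filter (coefficient 0.3, emulating the autocorrelation
of band-pass-filtered BOLD) that preserves the cross-sectional
covariance; each node series is standardized afterwards. If the block
matrix is not positive definite, eigenvalues are floored at 1e−6, the
matrix reconstructed and rescaled to unit diagonal — deterministic, and
a no-op for valid configurations already positive definite.

Defaults emulate the study conditions this pipeline addresses: 90 nodes
in four modules of (22, 22, 26, 20), 30 subjects per group, 215 time
points, two hub nodes per module. Group correlation baselines are
control (ρ_within 0.32, ρ_between 0.20, ρ_hub 0.30) and patient
(0.27, 0.23, 0.33). The baselines were calibrated once against
qualitative features of real cohort analyses — proportionally
thresholded networks must retain both within- and between-module edges
(so ASMI is defined for every module pair), roughly ten connector hubs
per subject, and a patient group that is still clearly modular — and the
patient deltas (−0.05 within, +0.03 between and hub) plant the
qualitative contrast of interest: lower modularity, higher inter-module
interaction, higher hub PC/WMD ratio in patients.

What the generator does not emulate: scanner physics, head motion,
physiological noise, hemodynamic convolution, spatial autocorrelation of
atlas regions, inter-subject variability in module membership, or
heavy-tailed edge-weight distributions. Passing tests therefore show
that the pipeline detects the planted effects under a Gaussian
block-covariance model at realistic sample sizes — not that effect
sizes or p-values transfer to any real cohort.

## Problem sizes in the test and acceptance runs

The test suite and `scripts/acceptance.py` use the package's
scaled-down profile — 100 Louvain runs per subject, 1000 permutations,
100 (or fewer) null networks, and cohorts of 10–30 subjects per group —
as the package's own default for routine verification; the study-scale
parameters (1000 runs, 5000 permutations, 1000 nulls) remain the
pipeline defaults for real analyses. Error-control checks run 200 null
replicates (NBS family-wise error) and 2000 replicates (permutation-p
super-uniformity); null self-consistency of γ, λ, σ averages 100 draws
with 20 nulls each.

## Known limitations

- The group aggregation step (averaging subject agreement matrices) is
  one reasonable choice among several; with very heterogeneous cohorts
  a median or trimmed aggregation might be preferable.
- Louvain resolution is fixed at 1.0 by default; the sensitivity of the
  template to resolution and τ is exposed via config but not swept.
- Negative-weight network analysis is out of scope: negative FC is
  rectified to zero before any graph metric.
- Lp on disconnected graphs excludes unreachable pairs rather than
  substituting a penalty; compare networks at equal sparsity only.
- The NBS implementation recomputes mean-difference statistics per
  permutation; a t-statistic option exists for the edge test but the
  component-forming threshold is always on the permutation p scale.
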