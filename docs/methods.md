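# Methods

## Data model

The pipeline consumes a processed community table: samples identified by
(site, depth, year-month) × features. OTU columns hold relative abundances
computed per sample over *all* OTUs before any filtering; environmental
columns (temperature, pH, DO, TN, TDN, TP, TDP, chl-a, precipitation,
discharge, turbidity) keep their raw scales and ride along as ordinary
features so the network stage can treat them as nodes. Dates are truncated
to year-month resolution — the design is monthly sampling.

The prevalence screen keeps a feature when its occurrence fraction
(value strictly greater than a detection threshold, default 0) is at least
`min_prevalence` (default 0.20) of the samples; environmental features are
always kept, and retained OTUs are **not** renormalized — they remain
fractions of the original whole community, which matters for the bloom rule
("share of total bacterial composition") and the function collapse.

## Local similarity analysis

Series preparation: interior gaps are filled by linear interpolation on the
month index; leading/trailing gaps take the nearest observed value (linear
interpolation is undefined beyond the observed range, and dropping edge
months would shrink the alignment span the duration filter depends on).
Values are then mapped to normal scores Φ⁻¹(rank/(n+1)) with average ranks
for ties; a constant series maps to all zeros and can never score.

The LS statistic is computed by two banded dynamic programs over positive
and negative partial sums of products, offset limited to |i−j| ≤ D. The
delay limit defaults to **D = 1 month**: monthly ecological couplings
longer than one month are rarely interpretable with 15 time points, and
D is configurable. The traceback records the chain attaining the maximum
(start indices and length); ties are broken deterministically by smaller
|delay|, then positive sign, then earliest start. A zero score (possible
only for degenerate constant input) is reported with sign `+`, delay 0 and
span length 0.

Significance: permutation of the time order of one series (the other held
fixed), with the add-one estimator p = (1 + #{LS_perm ≥ LS_obs})/(1 + R).
The default **R = 2000** makes the floor 1/2001 ≈ 0.0005, so the strict
screen p < 0.001 is attainable (R = 999 would put the floor exactly at
0.001 and nothing could pass). Whole-series permutation (no blocks) is the
appropriate null for short monthly series. Per-pair random streams are
derived from the pair identity (CRC of the sorted feature names mixed with
the global seed), so results do not depend on pair enumeration order. An
optional Benjamini–Hochberg q-value can be attached downstream but is off
by default; the screening rule is the raw p-value.

The permutation kernel exploits the band structure: each diagonal of the
DP table is an independent one-dimensional chain, so all permutations are
scored with (2D+1)·n vectorized max/add steps (~1–3 ms per pair for
n = 15, R = 2000).

## Network construction and consensus

Per series set, an edge requires p < α (default 0.001, strict) **and** an
alignment lasting more than `min_span` months (default 6, strict `>`;
an inclusive comparator is available). Nodes are features incident to at
least one kept edge.

Consensus ("recurrent") merging counts recurrence per **(pair, sign)**: a
positive and a negative association between the same pair are different
edges and never pool evidence. Delay equality is *not* required — per-site
delays wobble with sampling noise — and the consensus delay is the modal
member delay (ties → smaller |delay|, then positive). An edge enters the
consensus at recurrence ≥ 3 of 6 by default. In the unlikely event that
both signs of one pair independently reach the threshold, the
better-supported sign is kept (ties → positive), because the consensus
graph is a simple graph. Consensus edges are always a subset of the union
of input edges, and raising the recurrence threshold can only shrink the
edge set.

## Topology panel

Signs are ignored for all topological metrics; the fraction of positive
edges is reported separately. Clustering is the mean local coefficient with
degree-<2 nodes contributing 0. Path length and diameter average/maximize
over *connected* pairs, with a disconnected flag (consensus networks keep
only incident nodes, but can still fragment). Heterogeneity is the
coefficient of variation of the degree sequence (population variance);
centralization is Freeman degree centralization Σ(k_max − k_i)/((N−1)(N−2)).

Random baselines are uniform **G(n, m)** graphs — exactly the observed
numbers of nodes and edges, not edge-probability matching — averaged over
100 replicates by default, with Monte-Carlo standard errors reported. The
small-world coefficient is SW = (C/C_R)/(L/L_R); SW > 1 flags small-world
structure. For an ER graph tested against its own ensemble SW is ≈ 1 (the
acceptance suite checks [0.8, 1.2]).

## Modules, roles, patterns, blooms

Louvain runs unweighted on the unsigned consensus graph (a single partition
of a signed network without a signed-modularity method matches how such
networks are usually summarized); LS-weighted detection is available behind
a flag. Node-order randomization is controlled by an explicit seed, so
partitions are reproducible; module labels are ordered by size. "Major
modules" are the largest modules whose cumulative node coverage reaches
85 % (configurable).

Zi uses the population standard deviation of within-module degree and is
defined as 0 when that SD is 0 (every member equally connected — no hubs by
construction). Pi = 1 − Σ_s (k_is/k_i)². Thresholds: peripheral (Zi ≤ 2.5,
Pi ≤ 0.62), module hub (Zi > 2.5, Pi ≤ 0.62), connector (Pi > 0.62,
Zi ≤ 2.5), network hub (both exceeded). Degree-0 nodes are excluded with a
warning (Pi is undefined).

Module monthly patterns min-max scale each non-cyanobacterial member OTU
across all samples ((x − min)/(max − min), constant → 0), then average over
member OTUs and the samples of each year-month.

Bloom labeling uses strict inequalities: share of the whole community
> 0.10 **and** chl-a > 15 µg/L, or share > 0.80 regardless of chl-a (the
dominance override covers winter blooms of dominant taxa at low
chlorophyll). Raising either threshold can only remove bloom calls.

## Function collapse

A function map assigns functions to taxon selectors; an OTU matches a
function when any rank label of its lineage (or its own id) exactly equals
a selector. Multi-function OTUs contribute fully to each function (the
standard convention for such databases), unmapped OTUs to none, and
functions with no member present are explicit zero rows. The per-module
function value is the summed relative abundance of matching member OTUs —
equivalently the module's function composition scaled by the module's total
OTU abundance. Columns are grouped by (module, month) by default, or per
sample. Three display normalizations are provided (none, per-group
fraction, min-max per function); none of them is claimed to be canonical.
The repository ships only a small synthetic toy mapping
(`mran/data/toy_functions.tsv`); any real mapping file can be supplied.

## Synthetic data generator

Per (site, depth), OTU latent log-abundances follow
z_i = b_i + √w·g_m + √(1−w)·h_i + ε, with module drivers g_m, smooth AR(1)
idiosyncratic terms h_i, white noise ε (sd `noise_sd`), and per-OTU
baselines b_i ~ N(0, `base_log_sd`²) giving a log-normal rank-abundance
profile. Drivers are annual-harmonic sinusoids (period 12/k months) taken
in frequency/quadrature pairs, so distinct module drivers are mutually
near-orthogonal over the window — phase-shifted copies of a single annual
sinusoid would make distinct modules strongly (anti-)correlated by
construction and unrecoverable in principle. The bloom module's driver
additionally carries a summer pulse.

Planted pairwise couplings form a disjoint matching within modules: the
partner series is a signed, lagged (±1 month for a configurable fraction)
copy of its mate plus noise. A disjoint matching keeps edge-recovery
precision well defined (chained couplings would create true transitive
correlations that look like false positives). Spurious couplings are
planted in exactly the first series set, so the recurrence screen provably
removes them. Latents are exponentiated, closed to compositions, the bloom
OTU is forced to its target summer share (default 0.4), and compositions
are resampled from a Dirichlet with concentration `α·p` (default α = 500).
Chl-a is affine in the bloom OTU share (2 + 40·share + noise), so the
default summer share puts chl-a at ≈ 18 µg/L — above the bloom threshold —
while non-bloom months sit near 2–4 µg/L. Missing months are masked at rate
`missing_month_fraction` (default 0.2, matching a ~69-of-90-sample design),
keeping each series' endpoints. Output is bit-identical for a fixed seed.

Defaults mirror the emulated study design: 3 sites × 2 depths × 15 monthly
time points, 200 OTUs (8 cyanobacterial), 11 environmental variables,
5 modules.

**What the generator does not emulate:** sequencing depth variation and
zero inflation, phylogenetic correlation, abundance-dependent detection,
non-stationary couplings, and real environmental drivers. Passing tests
demonstrate correctness of the inference machinery under the planted model,
not field performance.

A known and deliberate property: compositional closure adds a shared
denominator term to every series, which attenuates *negative* and *lagged*
couplings more than positive synchronous ones (the common-mode component is
positively shared and misaligns under lags). Detection power on planted
edges is therefore highest for positive zero-delay couplings; the power
check in the test suite uses exactly those, while the consensus tests keep
the mixed edge population and assert the precision/recurrence properties
that do not depend on per-edge power.

## Problem sizes in tests and the acceptance script

End-to-end runs use 50 OTUs × 15 months × 6 series sets with 2000
permutations per pair (≈ 7 400 pair tests per run), null calibration uses
1000 independent pairs at 999 permutations, and oracle comparisons use
200 random instances each; these sizes give stable statistics while keeping
a full run around half a minute. The Erdős–Rényi self-consistency check
runs at the consensus scale reported for the emulated study (n = 362,
m = 2072, 100 replicates).
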