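# Methods

## Model and assumptions

The package treats a genome-scale metabolic network as a steady-state flux
system: stoichiometric matrix `S`, flux bounds, and a GPR (gene-protein-
reaction) boolean rule per reaction. Every reversible reaction is split
into a mirrored forward/reverse pair so all fluxes are non-negative; this
is what makes the expression-weighted flux-sum constraint linear. Exchange
and demand reactions are detected structurally (single-metabolite
stoichiometry), never by id prefix. No growth or maintenance objective is
imposed and nutrient exchanges are open by default: the method reads out
*relative* capacity changes driven by expression, not absolute rates.

The core assumption is that flux through a reaction of interest (ROI) is
informed by the coordinated expression of enzymes along linearly coupled
pathway segments around it — not only its cognate enzyme (too noisy, often
regulated post-translationally) and not the whole network (distant
expression dilutes the local signal). The LP encodes this by charging each
unit of flux a price `decay(d_j) · penalty_j` against a fixed budget
(the flux allowance) while maximizing the ROI flux.

## Expression mapping

Gene levels must be non-negative and unscaled (log2 data is inverted with
`unscale_log2`). GPR collapse uses min over AND (complex limited by its
scarcest subunit) and sum over OR (isozymes add). Measurement status is
tracked per reaction: *complete* (all GPR genes measured), *partial*
(unmeasured OR branches are excluded; an AND with a measured sibling uses
the measured minimum), *missing* (no measured gene, or no GPR). Zeros are
data; absences are not — the distinction survives the whole pipeline.
Relative expression is each reaction row divided by its own
across-condition maximum, so every measured row attains 1 somewhere and
penalties are scale-free (multiplying a gene row by any constant changes
nothing).

Penalties are `1 / max(rel, eps)`. *Missing* reactions get penalty 0,
i.e. their flux is free: this is deliberate, and is what lets an ROI
without any expression data be predicted from its neighborhood rather than
being biased toward zero.

## Distances

Directed reactions are adjacent when one produces a metabolite the other
consumes; the two directions of one base reaction are never linked. A hop
costs `max(1, 1 + log2(deg(m)/2))` for the cheapest bridging metabolite
`m`, where the degree counts distinct base reactions producing plus
consuming `m`. Degree 2 (strict linearity) costs exactly 1, so the
weighted distance reduces to the naive "reactions between plus one" count
along linear pathways; hubs grow logarithmically, which empirically keeps
side-metabolite shortcuts (phosphate, ATP) from gluing unrelated pathways
together without any hand-curated side-metabolite list.

The neighborhood distance from an ROI to reaction *r* is
`min(d(ROI→r), d(r→ROI))` over directed (mass-flow-consistent) paths, so
both the routes feeding the ROI and those draining it are integrated,
while two reactions that merely share a downstream consumer stay at
infinite distance. Each single-source row is a Dijkstra run and satisfies
the directed triangle inequality; the two-leg minimum is not itself a
metric, which is acceptable because only per-ROI rows are ever used. This
directional asymmetry is load-bearing: a mandatory co-product drain's
*sibling* supply routes are at infinite distance, so their (possibly poor)
expression does not leak into the ROI's score — exactly the failure mode
of whole-network resistance scoring that the co-product fixture probes.

`effective_boundary` converts a weighted boundary into an interpretable
pathway length: the maximum naive distance among reactions inside the
weighted radius.

## The LP and its parameters

`FP = max v_roi` subject to `S v = 0`, `0 ≤ v ≤ ub`, `Σ w_j v_j ≤ A`,
solved with scipy's HiGHS backend. Parameters that matter:

- **allowance A** (flux a.u., default 1): pure scale; rFP is invariant to
  it (tested at 0.1/1/10), so the value is arbitrary.
- **decay family**: `power` (order n; n = 0 integrates the whole network;
  the original formulation), `hard_boundary` (1 inside b, 0 outside) and
  `exponential` (1 inside b, `2^-(d-b)` outside). Standard configuration:
  exponential, b = 6, weighted metric — the soft tail makes predictions
  insensitive to the exact boundary choice.
- **eps** (default 1e-3): penalty cap `1/eps`. For bulk data 1e-3 is
  effectively "a zero-expressed mandatory reaction blocks the route". For
  single-cell data we recommend **eps = 0.1**: a dropout zero is uncertain
  evidence (the transcript may be present but undetected), and a cap of 10
  lets a well-expressed pathway outvote one dropped-out mandatory
  reaction. With the harsh cap, pathway integration is *less* robust to
  dropout than plain reaction expression (one zero anywhere on the route
  crushes the LP); with the moderate cap it is more robust, which is the
  behavior the dropout simulation demonstrates.
- **upper bounds** (default 1000 a.u.): slack by design. If every weighted
  reaction on an unbounded route has weight 0 the optimum sits at this
  bound and is flagged `clamped` rather than reported as a meaningful
  optimum.
- **tolerance** (1e-9): below it `FP_super` counts as zero and rFP is
  undefined (NaN), never 0/0.

A reversible ROI is scored per direction, reported separately. The ROI's
own penalty enters the weighted sum at distance 0; excluding it (penalty
override 0) is supported and the pathway signal survives, which is the
basis of gap-filling and override predictions.

## Baselines

All baselines share the super-condition normalization so scores are
comparable in [0, 1] with higher = more capacity. Reaction expression is
the ROI's own relative expression. Compass- is the two-stage resistance
score: maximize `v_roi`, then minimize penalty-weighted total flux subject
to retaining 95% of that optimum (Compass's own default
fraction); score = super-condition resistance over
condition resistance. It uses the same penalties as the main method for a
fair comparison, applies no distance decay and no cell pooling. The
decayed variant multiplies stage-2 weights by a power decay over naive
distances (order 2.5 reference point); order 0 recovers Compass- exactly.
The original-FPA baseline is the same LP code path with power decay and
naive distances. The Compass- normalization uses the plain resistance
ratio (no log transform); since super-penalties (all 1) bound condition
penalties from below, the ratio lands in [0, 1] without clipping in
practice.

## Statistics

Pearson correlations are tested row-wise with the two-tailed t-based p;
BH-FDR is applied over exactly the set of testable rows (constant or
too-short rows are excluded and flagged — family membership is explicit,
never inferred). Significance is FDR ≤ 0.05 with PCC > 0. Pathway
coexpression strength is the median of all pairwise member PCCs; the
pathway profile is the per-condition median of member relative
expressions. The cross-informing rate bins connected reaction pairs into
equal-count bridging-degree bins (default 8; the binning is a package
choice, as only approximate grouping is specified) and reports the
significant fraction per bin. The permutation test shuffles reaction
labels (rows keep their values), uses the pseudo-count form
`p = (1 + #{null ≥ obs}) / (1 + n_perm)` so p is never 0, and is seeded.
Cell-type enrichment uses median fold change and a two-sided Wilcoxon
rank-sum with tie-corrected normal approximation (single-cell zeros are
heavily tied); the comparison population always excludes the top-ranked
cell type (or the runner-up when the tested type is itself top), so one
dominant metabolic tissue cannot mask enrichment elsewhere. Flags:
FC > 1.2 and p < 1e-10. ΔrFP is the row-median-centered group score with
±0.2 enrichment/depletion thresholds.

## Synthetic data

The generator emulates the statistical structure of the study scenarios,
not any real organism. Expression is log-normal: pathway member genes
share a per-condition latent factor f ~ N(0,1) with
`log2 level = sqrt(rho)·f + sqrt(1-rho)·noise_sd·ε`, giving pairwise
coexpression rho at the default noise_sd = 1; true pathway flux is
`beta·f + flux_noise_sd·η`, carried equally along the chain. Defaults
(rho = 0.8, beta = 1, 25 conditions, pathway length 4, background chain 6,
decoy branch 4) define the simulated study conditions. Dropout is
post-hoc Bernoulli zeroing; nothing is imputed. Templates: `linear`,
`branched` (noisy upstream background + coexpressed pathway + data-less
terminal ROI + independent decoy branch), `hub` (configurable-degree hub
metabolite), `glycogen` (two branches sharing one GPR), `coproduct`
(mandatory lumped drain fed by a separate poorly expressed route).

What passing these simulations does *not* show: real proteomes have
thousands of reactions, promiscuous enzymes, compartments, and expression
that violates the log-normal single-factor model; the fixtures demonstrate
the mechanisms (pathway recovery, boundary titration shape, hub
filtering, drain decoupling, dropout behavior), not field performance on
any particular dataset.

## Numerical and design notes

- LP feasibility tolerance is the solver's (HiGHS, ~1e-9); results are
  asserted at 1e-6. Infeasible ROIs report FP = 0 with a status flag;
  per-ROI failures never abort a batch.
- Dijkstra tie-breaking is irrelevant: only distances, not paths, are
  consumed.
- Distances are computed once per ROI direction and reused across
  conditions; one LP per condition plus one super-condition LP.
- The boundary-titration and parameter-recovery simulations run at
  pathway length 4 with 10–50 seeds and 25 conditions — sizes chosen so
  the full suite stays interactive while the binomial error bars on win
  fractions stay small.
- Known limitations: no quantitative uptake constraints (bound overrides
  are supported generically but no media tables ship); no
  variance-stabilizing transformations for tissue data; no MILP-based
  alternatives; the exact degree-weight and effective-boundary formulas
  are this package's own calibration of the qualitative rule "linear
  links cost 1, hubs cost more, sub-linearly".
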