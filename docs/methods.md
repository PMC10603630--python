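# Methods

This note documents the models implemented in `phylocons`, the numerical
and design choices behind them, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Trees

All computations run on a rooted, dated phylogeny whose branch lengths are
carried verbatim in million years (Ma); nothing ever rescales them.
Polytomies are accepted by the conservation metrics (ED, PD), which only
need descendant-tip counts; the biogeographic likelihoods require a
strictly binary tree and refuse anything else. Zero-length branches are
allowed with a warning; negative lengths are rejected at parse time.
Parsing (newick and NEXUS with `translate` tables) is delegated to
dendropy; rootedness is taken from the file as written and no rerooting is
ever performed silently. Unquoted underscores are preserved by default
(the convention of most phylogenetic pipelines); the strict
underscores-as-spaces dialect is available via a flag.

Pruning preserves the original root, so root-to-tip distances — and hence
single-taxon PD — are unchanged; degree-2 nodes created by pruning are
suppressed with their branch lengths summed, which keeps all pairwise tip
distances exact.

Internal nodes are matched *across* trees (the members of a posterior
sample) by their descendant-tip label set. This is the only node identity
the package uses, so averaged node posteriors are well defined even when
topologies differ: a clade absent from a sampled tree simply contributes
nothing to that clade's average.

## Conservation metrics

**Fair-proportion ED.** Each edge's length is divided equally among the
tips descending from it; a tip's ED is the sum of its shares along the
root path. This makes per-species ED an exact partition of the tree's
total branch length — the test suite asserts Σ ED = total PD to 1e-9
relative on hundreds of random trees, and cross-checks the accumulation
against an independent per-tip path traversal. Only the fair-proportion
measure is implemented (no equal-splits variant). Mean ED is therefore
always total PD divided by species count.

**GE and EDGE.** IUCN categories map to integers LC=0, NT=1, LR/cd=1
(accepted spelled either `LR/cd` or `LRcd`), VU=2, EN=3, CR=4. Categories
outside this closed vocabulary (DD, NE, EX, EW) are rejected rather than
guessed: the score is undefined for them and imputation policy belongs to
the caller. EDGE = ln(1+ED) + GE·ln 2 with natural logs; each Red List
step adds ln 2, doubling the priority odds. Ties in the EDGE ranking break
by ED, then species name.

**PD and extinction scenarios.** Faith's PD of a taxon set is the branch
length of the union of root-to-tip paths (`include_root=True`, the
default), so a single taxon retains its full root-to-tip history; the
MRCA-spanning convention is exposed as a flag because R implementations
differ by version on this point. Extinction scenarios prune the survivors,
recompute total PD, and report the loss fraction on unrounded values,
rounding only for display.

**Grid-cell PD.** Range polygons (WGS84 decimal degrees) are rasterized
onto a grid anchored at integer multiples of the resolution, cells indexed
by SW corner and half-open on their N/E edges so nothing is double
counted. Presence requires nonzero-area intersection with the cell —
boundary contact does not count; a centroid-in-polygon rule is available
because published conversions do not always state which rule they use.
Multi-polygons are rasterized part by part. No equal-area correction is
applied; everything stays in decimal degrees, matching how such maps are
usually projected for continental-scale raptor atlases. Polygon input is
GeoJSON (species attribute `sci_name` by default, as in IUCN downloads);
map output is CSV or GeoJSON of cell polygons.

## DEC-family biogeography

**State space.** Ranges are subsets of the area set, size-bounded by
`max_range_size`, ordered null-first then by size and lexicography so
state indices are stable. The hard cap of 8 areas reflects the 2^n state
growth and the empirical fact that ancestral resolution degrades quickly
with many areas.

**Anagenesis.** rate(R → R∪{a}) = |R|·d (each occupied area is a source),
rate(R → R\{a}) = e per occupied area; the null range is absorbing.
Transition probabilities use scipy's Padé scaling-and-squaring matrix
exponential with a post-hoc row-sum check at 1e-10 and clipping to [0,1];
the test suite cross-checks against an independent truncated-Taylor
oracle.

**Cladogenesis.** For each parent range the model defines a set of ordered
daughter pairs, each event instance weighted 1, normalized per parent:

* *DEC*: single-area parents speciate sympatrically (R,R); widespread
  parents allow subset sympatry ((a,R) and (R,a) for each a ∈ R) and
  vicariance with a single-area side ((a,R\a) and (R\a,a), deduplicated —
  a two-area parent yields exactly 6 events of probability 1/6.
* *DIVALIKE*: sympatry only for single-area parents; widespread parents
  split by vicariance into any two nonempty disjoint parts, both sides
  allowed to be widespread ("widespread vicariance"); no subset sympatry.
* *BAYAREALIKE*: both daughters inherit the parent range exactly.
* *+J*: adds founder events (b,R) and (R,b) for every single area b
  outside the parent, each weighted j against weight 1 for every non-jump
  instance. j=0 reproduces the base model bit-for-bit. This
  per-event-instance weighting is the simplest published convention.

**Likelihood and root.** Felsenstein pruning over range states, with the
daughter partials combined through the event table at each node. The root
is averaged uniformly over non-null ranges (the classic LAGRANGE
convention, no conditioning on survival). This choice shifts lnL — and
hence AICc — by a constant relative to tools that weight the root
differently, which matters when comparing absolute AICc values across
implementations but never affects within-analysis ranking. Both the root
weighting and the AICc sample-size convention (n = number of tips) are
deliberately plain and documented here because neither is universal.

**Fitting.** Bounded Nelder-Mead from three documented starts
((0.01,0.01[,0.01]), (0.1,0.1[,0.1]), (0.001,0.001[,0.5])) with
d,e ∈ [1e-12, 5]/Ma and j ∈ [0,3]; the best of the starts is kept and an
error carrying the best-so-far is raised if no start converges. AICc is
computed from the closed form with k=2 (base) or k=3 (+J).

**Ancestral ranges.** Marginal probabilities at each internal node (the
parent range at the instant before cladogenesis) come from an up-down
pass: the downward conditionals from pruning are multiplied by an upward
message routed through the node's stem and its sibling's subtree via the
event table. The implementation is validated against exhaustive
enumeration over all internal-state/event assignments on 3-tip trees for
every model, with and without jumps, to 1e-8.

**A note on estimating e.** Extinction is weakly identified in this model
family. Contraction along branches is confounded with subset-sympatry
cladogenesis (both produce single-area daughters from widespread
ancestors), and data sets conditioned on all lineages surviving carry
little signal for e; maximum-likelihood fits therefore routinely drive ê
to its lower bound even on data simulated with e > 0 — the recovery
experiment in the test suite documents exactly this, with d̂ recovering
well (median relative error ≈ 0.14 at the study size) while ê collapses
to ~0. Users should treat fitted e values near 1e-12 as "unresolved, small"
rather than as evidence of zero extinction.

## Bayesian multistate MCMC

With the maximum range size forced to one area, ancestral-area estimation
reduces to a single multistate character under an equal-input model,
q(i→j) = μ·π_j, whose transition probabilities have the closed form
P_ij(t) = π_j + (δ_ij − π_j)·e^(−μt). Rate heterogeneity is modeled by a
Gamma(α) multiplier discretized into 4 equal-probability categories (mean
category rates via the incomplete-gamma identity) and averaged in the
likelihood — the natural reading of an "F81 + Gamma" setting for a single
character, where Gamma acts across branches/rate draws rather than across
sites.

The sampler is random-walk Metropolis–Hastings on (μ, α) with log-normal
proposals (Jacobian-corrected) and, optionally, on π with a
Dirichlet-neighborhood proposal; priors are Exponential(mean 0.1/Ma) on μ,
Exponential(mean 1) on α, flat Dirichlet on π. Every generation draws a
tree uniformly from the supplied sample, so node posteriors integrate over
phylogenetic uncertainty. At each thinning point the analytic node
marginals (up-down pass, category-weighted) are computed and one state per
node is drawn and accumulated; chains are pooled after discarding the
burn-in fraction. Output is reproducible bit-for-bit given (seed,
settings, inputs); chain seeds derive from (seed, chain index).

Default settings mirror a typical published protocol (10 chains, 1e6
generations, thinning 100, 25% burn-in); the `fast` preset (2 chains,
2e4 generations) is what the tests and the acceptance script run, chosen
so the whole posterior fits in well under a minute on one core while still
yielding ~300 pooled draws. Widespread species must be collapsed to a
single "primary" area under this coding; the packaged vulture coding
assigns both widespread vultures to South America (the bulk of their
ranges) and reports that choice alongside results, since it is a modeling
decision, not data.

## Synthetic data

The generators exist so every stage is testable without downloads:

* **Yule trees** — pure-birth, ultrametric, seed-deterministic; the root
  height matches the Σ 1/(kλ) expectation (asserted at 3σ over 500
  trees). Real clades are not Yule; these trees provide neutral, scalable
  topology/branch-length substrates, not realistic diversification.
* **Forward DEC histories** — Gillespie simulation along branches plus
  event-table draws at nodes, recording true node ranges and the
  anagenetic event count. Replicates where any lineage hits the null range
  are rejected and resimulated (count reported). This matches how such
  simulations are usually run but means simulated data sets are
  survivorship-conditioned while the fitted likelihood is not — one
  reason ê is biased low (see above).
* **Range polygons** — axis-aligned rectangles on a 0.5° lattice. They
  exercise the rasterization contract exactly but share nothing with the
  fractal, fragmented geometry of real IUCN polygons, so spatial tests
  validate bookkeeping, not cartographic realism.
* **The vulture fixture** — topology, tip names, Red List categories and
  both area codings follow the published account of the Cathartidae; the
  branch lengths are synthetic round-number node heights guided by
  published divergence-date prose and rescaled so total length is exactly
  62 Ma. Consequently mean ED (= 62/7) and quantities driven by gross
  tree shape land close to published values, while per-branch quantities
  can deviate by a few Ma / percentage points. Outputs on this fixture
  are illustrative of the pipeline, not reproductions of the published
  per-species numbers. The two geography codings were reconstructed from
  the species' described distributions and are editable data, not
  published matrices.

## Problem sizes and tolerances

The test suite and acceptance script size their experiments to run on one
core in a few minutes: 200 random trees for the metric invariants; all
3-tip shapes × 27 two-area codings × a 3-point (d,e) grid for the
enumeration cross-check (1e-8 absolute); 20 forward-simulated replicates
on one 50-tip Yule tree (birth rate 0.1/Ma, three areas, root range one
area) for parameter recovery; and the fast MCMC preset for the Bayesian
stage. Clado-table normalization is enforced at 1e-12, marginal-vector
normalization at 1e-9, matrix-exponential row sums at 1e-10.

## Known limitations

* No time-stratified areas, dispersal-multiplier matrices,
  distance-scaled dispersal, or biogeographic stochastic mapping.
* No probabilistic EDGE2, range-weighted ED, or expected-PD-under-
  extinction-probability metrics.
* Shapefile input is not supported; convert ranges to GeoJSON first.
* The DEC likelihood does not condition on survival; absolute lnL/AICc
  values are comparable only within this package's conventions.
* MCMC convergence is the user's responsibility for non-default settings;
  the package reports parameter traces but computes no diagnostics.
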