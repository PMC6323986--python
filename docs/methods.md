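# Methods

## Network model and score combination

An association network is an undirected graph of proteins; each edge
carries seven per-channel confidences in [0, 1] plus a combined
confidence. Absent evidence is scored 0, never missing; self-loops are
rejected at parse time (warning, not fatal); edges are canonicalized with
the lexicographically smaller endpoint first.

Channel combination is a noisy-OR with prior correction: each enabled
channel score *s* is first stripped of the prior *p*,
s′ = max(0, (s − p)/(1 − p)), the corrected scores are combined as
1 − Π(1 − s′ᵢ), and the prior is re-added. The default prior is 0.0,
which reduces to a plain noisy-OR; the organism-specific prior of a real
deployment is a configuration concern, and the zero default keeps the
arithmetic of the worked examples exact. The combination is
permutation-invariant, monotone in every enabled channel, and never below
the largest enabled score when the prior is 0. Within a channel, direct
and transferred (inter-organism) sub-scores are merged by the same
noisy-OR; no published rule fixes this merge, so it is documented as a
convention of this package.

The curated-database channel bypasses statistical calibration entirely:
every distinct pair named by curated pathway or complex co-membership
records receives the uniform confidence 0.900, with duplicates collapsed.

Confidence presets: `highest` = 0.900, `high` = 0.700, `medium` = 0.400,
`low` = 0.150. Only `highest` is a published constant; the rest are the
conventional ladder and can be overridden numerically.

Score dialects: integer 0–1000 ("string1000", values divided by 1000 on
read) and float 0–1; `auto` selects string1000 iff any score exceeds 1.
Rows naming the same unordered pair with different scores keep the larger
combined score, with a warning.

## Diffusion state distance

With W the symmetric matrix of combined confidences and P = D⁻¹W the
random-walk transition matrix, the k-step visit-count profile of node *u*
is He_k(u) = Σ_{t=0..k} e_u Pᵗ and DSD_k(u, v) = ‖He_k(u) − He_k(v)‖₁.
On a connected non-bipartite graph the profile differences converge, and
the limit has the closed form

    DSD(u, v) = ‖(e_u − e_v)(I − P + W_π)⁻¹‖₁,

where W_π stacks the stationary distribution π (for this reversible walk,
πᵢ ∝ Σⱼ wᵢⱼ) in every row. The closed form is the default mode: it is
parameter-free, deterministic, and defined even when the finite-k sum
oscillates (bipartite graphs have a period-2 component, so the finite-k
oracle is only compared on non-bipartite test graphs). The matrix is
inverted densely up to 5,000 nodes; beyond that, rows of the inverse are
obtained by per-column LGMRES solves at tolerance 1e-8.

Disconnected input is never silently patched with infinite distances: the
caller must restrict to the largest connected component, for which a
helper is provided, and the CLI does this automatically (logged).

Properties verified by the test suite: metric axioms on random connected
graphs, equivariance under node relabeling, invariance under uniform
rescaling of all edge weights, DSD = 1 on the two-node graph, and
agreement of the closed form with the finite-k oracle at k = 10⁴ to
better than 1e-6 on graphs of up to 50 nodes.

## Module discovery

The DSD matrix is clustered agglomeratively with unweighted average
linkage (UPGMA), implemented via the Lance–Williams update. Ties at the
minimal inter-cluster distance are broken toward the lexicographically
smallest (cluster-id, cluster-id) pair, with ids assigned in leaf order
and then merge order; this makes the dendrogram bit-reproducible across
platforms. On tie-free inputs the result coincides with
scipy.cluster.hierarchy's average linkage, which the tests use as an
independent cross-check. Average linkage is monotone, so merge heights
are non-decreasing.

Module extraction takes **all** internal nodes of the dendrogram whose
leaf-set size lies in [5, 200] (both bounds configurable), not a single
flat cut: the result is a nested, multi-scale collection, which is what
the per-framework enrichment stage expects. Emitted sets are laminar
before deduplication; duplicate member sets keep the lowest-height
instance. Sets are labeled `module_####` in merge order with the linkage
height recorded in the description, under the framework label
`network_modules`.

## Enrichment statistics

**ORA.** Upper-tail hypergeometric probability of an overlap at least as
large as observed, with the set intersected with the background first and
the query required to be a subset of the background.

**AFC.** For a set with k members present among the n input genes, the
observed statistic is the mean of their values. The null is the mean of
k genes drawn uniformly without replacement from the input genes — the
randomization universe is deliberately the submitted list, not a larger
organism universe. When C(n, k) ≤ `exhaustive_limit` (default 100,000)
all subsets are enumerated and the tail probabilities are exact; larger
instances use Monte-Carlo with `n_perm` draws (default 10,000, seed
mandatory) and the add-one correction p = (1 + #extreme)/(1 + n_perm),
which keeps p ≥ 1/(1 + n_perm) and makes the null p-value distribution
uniform up to discreteness. The reported p is two-sided (doubled smaller
tail, capped at 1) with both one-sided tails also exposed; the reported
direction is the smaller tail. Tail comparisons use a relative 1e-12
tolerance so that exact ties (e.g. all values identical) count as
extreme, giving p = 1. Adding a constant to all values shifts the
statistic but leaves the p unchanged.

**KS fallback.** Permutation AFC is quadratic-ish in set size at fixed
precision, so sets with more than `large_set_threshold` members in the
input (default 1,000) are tested by converting values to ranks (average
rank on ties) and comparing in-set against out-of-set ranks with a
two-sided two-sample Kolmogorov–Smirnov test — exact when
k(n − k) ≤ 10⁴, asymptotic otherwise. A one-sample variant (in-set ranks
against the uniform distribution) is available behind a flag; neither
variant claims to reproduce any third-party service numerically, since
the exact design of deployed fallbacks is not published. Note that with
one in-set gene at the extreme rank among ten, the two-sample statistic
is D = 1 with exact p = 0.2 (verified against exhaustive placement
enumeration).

**Multiple testing.** Benjamini–Hochberg step-up within each framework
separately, never pooled: classification frameworks overlap heavily, and
pooling would let a dense framework distort the FDR of a sparse one. The
library never thresholds significance; filtering (e.g. q < 0.05) is a
reporting-layer concern.

## Synthetic data

`make_modular_network` samples a planted-partition graph: within-block
pairs get edges with probability `p_in` = 0.8 and confidences from
Beta(6, 2) (high mode, ≈ 0.75 mean); between-block pairs with
`p_out` = 0.05 and Beta(2, 6) confidences, all clipped to (0, 1]. The
Beta shapes mimic the skew of confidence scores without claiming any
empirical distribution. The largest connected component is returned with
the planted blocks restricted to it. `make_value_table` draws background
gene values from Normal(0, sd) and planted genes from Normal(δ, sd); the
defaults used throughout the tests are δ = 2, sd = 1, 20 planted genes
among 1,000.

What the generator does **not** emulate: organism-scale graphs (tens of
millions of proteins), empirical score distributions, degree
heterogeneity, overlapping or hierarchically nested true modules, and
correlated gene values. Passing tests therefore demonstrate correctness
of the algorithms and calibration under a clean generative model, not
performance on real organism networks.

## Study sizes used in the verification suite

Chosen once as desk-scale renditions of the stated conditions: the AFC
null calibration tests 2,000 random size-20 sets over 1,000
standard-normal genes at 999 permutations per set; the power study runs
50 replicates of the δ = 2 planted set among 19 random decoy sets at
1,999 permutations (the planted set must reach q < 0.05); module
recovery runs 50 planted-partition replicates of two 20-node blocks and
requires Jaccard ≥ 0.9 against both blocks in at least 95% of
replicates; the Monte-Carlo/exhaustive agreement check uses instances
with C(n, k) ≤ 10⁴ at 10⁵ permutations and tolerance 0.01.

## Numerical choices and degenerate inputs

- DSD matrices are symmetrized (averaging with the transpose) and the
  diagonal zeroed after the solve; validation tolerates 1e-9 asymmetry.
- UPGMA treats exact floating-point equality as a tie; DSD inputs
  essentially never tie, and the documented tie-break exists for crafted
  or degenerate matrices.
- AFC sets with empty intersection and KS sets with degenerate in/out
  splits are skipped with a logged warning, not an error: a genome-wide
  run should not abort because one annotation term misses the input.
- Empty module collections are valid output (a 4-leaf dendrogram has no
  cluster of size ≥ 5).
- CLI exit codes: 0 success, 2 input error, 3 numerical failure. Every
  run writes a `manifest.json` with all materialized parameters; reruns
  with the same manifest are byte-identical.

## Known limitations

- No channel evidence is computed from raw data (genomes, expression,
  literature); the package models and combines already-derived scores.
- No interolog transfer, no ontology (true-path) propagation, no
  identifier cross-mapping: gene matching is exact-string, case-sensitive
  (an opt-in uppercase hook exists), and namespace mismatches fail loudly.
- Directed networks and capacitated/augmented DSD variants are out of
  scope.
- The dense DSD solve bounds practical network size to a few thousand
  nodes on a workstation; the iterative path above 5,000 nodes trades
  time for memory but has not been profiled at organism scale.
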