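# Methods

## Growth model

A network grows from a star on `m0 = m + 1` nodes (centre = root,
node 0).  Each step `j` adds node `j` with up to `m` links:

1. Existing nodes are ranked by degree (descending), then by depth `R`
   along parent pointers (ascending; the root has `R = 0`), and
   uniformly at random among remaining ties.  The tie permutation is
   drawn fresh every step.  The candidate pool F is the top
   `n_F = max(1, ceil(f · j))` ranked nodes; degrees are frozen at the
   start of the step.
2. `m` candidates are drawn independently from F with probability
   `k_i / Σ_F k_s`.
3. Each candidate `i` is resolved through the redirection rule: if
   `k_i ≤ k_{p(i)}` (or `i` is the root) the link attaches to `i`,
   otherwise to the parent `p(i)`.  Duplicate resolved endpoints
   collapse to a single edge, so a node may arrive with fewer than `m`
   links; the first endpoint becomes the new node's parent and
   `R(j) = R(parent) + 1`.

Draw independence (step 2) is a deliberate modelling choice for
`m > 1`: duplicate draws concentrate on hubs exactly when `f` is small,
which is what pushes the mean degree below `2m` there (measured
⟨k⟩ ≈ 3.9 at `m = 2, f = 0.1` against the BA value 4) while leaving it
at `2m` in the `f = 1` limit.  For `m = 1` the distinction is vacuous
and the result is always a tree.

**Ranking interpretation.**  `R` is the depth along parent pointers,
not the arrival index; distinct nodes share an `R`, which is what makes
the random tie rule meaningful.  Arrival order is kept separately (node
ids are arrival indices).

**Rounding of the pool size** uses `ceil` with a floor of one
candidate, so the pool is never empty for any `f > 0`; the ceiling is
evaluated with a 1e-9 guard against binary-float fuzz in `f · j`.

**Pool closure.**  If a node belongs to F, its parent does too (the
parent ranks at least as high: equal-degree parents are shallower,
higher-degree parents rank above).  `pool_parent_fraction` measures
this empirically; it is 1.0 in every configuration we generate, and the
tests assert ≥ 0.99 rather than enforcing closure structurally.

### Sampling implementation

A literal implementation re-sorts all nodes every step (O(N² log N)
per network).  The generator instead maintains, incrementally:

* a degree-descending permutation of the nodes with contiguous degree
  classes (constant-time updates under "degree += 1"),
* per-class depth histograms, and
* the flat edge-endpoint list, in which node `v` appears `k_v` times.

The pool cut is then read off in O(1): everything above the boundary
degree `d*` is certainly in F, complete shallow-depth groups of the
`d*` class are in F, and one depth group is partially in F (a uniform
random `s`-subset of `g` nodes).  A candidate is drawn by rejection
from the endpoint list — a proposal arrives degree-proportionally and
is accepted with its pool-membership probability (1, or `s/g` for the
partial group, realised lazily so that repeated proposals within one
step see a consistent subset).  Because every realisation of the pool
has the same total degree, this reproduces the literal law exactly; a
test compares the fast sampler against the closed-form marginal and
against the literal rank-and-sample path on the same snapshot.  A
bounded rejection count falls back to explicit pool materialisation
(never observed in practice; pool degree mass is a large fraction of
the total for all `f`).

Cost: ~1 s per 100 000-node tree on one core; memory is linear.

## Topology estimators

* **Degree curves.**  `p(k)` and the cumulative `P(k) = #{k_i ≥ k}/N`
  over observed degrees.
* **CCDF exponent β.**  OLS of `log10 P(k)` on `log10 k` over
  `k ∈ [kmin, k_q]`, where `k_q` is the degree at the 0.999 quantile
  (the extreme hub tail visibly leaves the line).  Default `kmin = 6`:
  the distribution head has not reached the asymptotic power law — on
  the exact BA tree closed form `P(k) = 2/[k(k+1)]` the local log-log
  slope is −1.5 at `k = 1` — and window scans against the known
  `β = f + 1` law show `kmin ∈ [3, 10]` recovers β to ≈ 0.02–0.05
  across the whole `f` range, with the bias growing quickly below
  `kmin = 3`.  The window is configurable and always reported.
* **Degree correlation α.**  `⟨k_nn(k)⟩` is the class average of the
  per-node mean neighbour degree.  The fit reads the scaling regime
  `k ≥ 10` over classes holding ≥ 5 nodes: the low-degree head of a
  growing tree saturates (every node retains a link toward the core),
  and a fit that includes it reports the head's shallow slope rather
  than the tail's power law (in the BA limit the tail is flat,
  α ≈ −0.05, while a full-range fit returns ≈ −0.15).  Small networks
  without three usable classes above the cut fall back to the full
  range.
* **Clustering.**  `C_j = 2x/(k_j(k_j − 1))`, defined as 0 for
  `k_j < 2` and averaged over all N nodes, so a tree has ρ = 0 exactly.
  Triangle counting is delegated to networkx.
* **Diameter.**  Exact double-BFS for trees; exact all-sources BFS for
  cyclic graphs up to 20 000 nodes; above that, the maximum
  eccentricity over double sweeps from the 20 highest-degree roots,
  labelled a lower-bound estimate in summaries.
* **Path length L.**  Trees: exact in linear time via the edge-cut
  identity `L = Σ_e s_e(N − s_e) / C(N, 2)` with `s_e` the subtree
  size under edge `e`.  Cyclic graphs: mean over BFS from
  `min(N, 1000)` uniformly sampled sources (seed-controlled; exact when
  the sample covers all nodes).
* **Ultra-small reference.**  `ln N / ln ln N`, defined for `N ≥ 16`.

## Box covering and fractality

A cover at distance parameter `r` repeatedly picks a uniformly random
uncovered seed and assigns to its cluster every uncovered node within
full-network shortest-path distance `r − 1`; `Qc` is the number of
clusters.  Distances are measured in the full network so that cluster
membership never depends on cover order.  Uniform seed selection is
implemented by scanning one pre-drawn permutation, which induces the
same law; the BFS kernel is numba-compiled with a numpy fallback.  The
curve runs over `r = 1 .. D + 1` (forced endpoints `Qc(1) = N`,
`Qc(D+1) = 1`) with mean and standard deviation over `n_rep = 10`
independent seed sequences by default.

Fractality is judged by least squares on the decaying part of the
curve, `r ≥ 2`: `ln Qc` vs `r` (exponential, scale `b`) against
`ln Qc` vs `ln r` (power law, dimension `D_f`), the winner being the
higher r².  The forced `Qc(1) = N` point is excluded; the saturated
`Qc(D+1) = 1` endpoint is kept, because the collapse to a single
cluster at small finite `r` is precisely the fast decay that a shallow
power law cannot produce — on the very short curves of the smallest-`f`
networks (D = 4) dropping it would leave three points on which either
law fits almost equally well.  Verdicts need at least four fit points;
shorter curves are reported "inconclusive" with both fits.

The iterative renormalisation of covered networks (collapsing clusters
into super-nodes) is not performed; the curve is read directly at every
`r`.

## Ensembles, seeds, provenance

Every replicate's seed derives from a stable SHA-256 hash of
`(master_seed, m, f, replicate)`, truncated below 2³¹, so any single
cell can be regenerated in isolation and identical specs yield
byte-identical CSV outputs.  Output files carry a content hash of the
scientific spec fields and the per-cell seed lists as `#` comment
headers.  Two scale presets exist: `paper` (N = 100 000, 10
replicates — the reference study conditions) and `desk` (N = 30 000,
5 replicates) for interactive work.

## What the generator does and does not emulate

Generated networks are connected simple graphs grown under the exact
model above; they reproduce the published reference behaviour —
`β = f + 1` within ±0.05, α from −1 to ≈ 0 across `f`, modal diameter
4 at `f = 0.1`, mean tree path length ≈ 11 at `f = 1`, ⟨k⟩ < 2m and
ρ > 0 at `m = 2` with small `f`, and exponential (non-fractal) cluster
decay for every `f`.  They are null models: real biological networks
additionally carry noise, sampling bias, motif enrichment and
degree-independent attachment effects that no parameter here emulates,
so agreement of a real network with an FPA ensemble supports only the
degree-sequence/growth-level description, never mechanism.

## Known limitations

* The `m > 1` multi-link semantics (independent draws, collapse of
  duplicate endpoints) is one defensible reading of an under-determined
  mechanism; `m ≥ 2` ensemble cells should be compared qualitatively,
  not cell-by-cell.
* Exponent fitting is deliberately the field's log-log line fit;
  maximum-likelihood (Clauset-style) estimation with KS-chosen `kmin`
  is out of scope.
* Diameter and path length of cyclic graphs beyond the exact-size
  limits are estimates (labelled as such); trees are always exact.
* Directed or weighted growth, node deletion, nonlinear attachment
  kernels and a time-varying `f` are not implemented.
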