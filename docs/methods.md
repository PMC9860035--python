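# Methods

## Model and assumptions

A group of `N` individuals plays a one-shot linear public-goods game while
embedded in a fixed directed network of institutional roles. A link
`i -> j` obliges `i` to monitor `j` and, if `j` free-rides, to punish `j`.
The model is egalitarian: every individual faces the same contribution
threshold `c_t`, and contributions benefit only the *other* `N - 1` members
(the `b`-multiplied pool is shared excluding the contributor), so unilateral
contribution is always a net private loss and universal free-riding is
always a Nash equilibrium.

Only two strategies are represented as first-class profile entries:
*threshold contributor* (pays exactly `c_t`) and *pure free-rider* (pays
nothing). Continuous contribution levels appear only inside the equilibrium
checker as deviation probes (below), reflecting the result that no
intermediate strategy survives at equilibrium.

Allocation rules, in priority order, for a contributor `i`:

1. monitoring: `k_out(i) / m`;
2. punishment reserve: any node with `k_out > 0` holds `c_p`, spends it
   split equally across the free-riders it monitors, and contributes it to
   the public good if it monitors none (the reserve is pure cost when spent
   on punishment — it never reaches the public good);
3. public good: the remainder `c_t - k_out/m - c_p` (or `c_t - k_out/m`
   when the reserve went unspent, or all of `c_t` for out-degree-0 nodes).

A contributor whose monitoring cost plus reserve exceeds `c_t` cannot fill
its role; this raises an explicit infeasible-role error naming the node.
Free-riding monitors never punish. A free-rider's loss is `p` times the
amount its contributor-monitors spend against it.

## Parameters

| name  | meaning                                   | constraint        | demo default |
|-------|-------------------------------------------|-------------------|--------------|
| `N`   | group size (nodes)                        | `>= 2`            | 6 or 12      |
| `b`   | public-goods multiplier (dimensionless)   | `>= 1`            | 4            |
| `m`   | individuals monitorable per unit resource | `> 0`             | grid         |
| `p`   | damage inflicted per unit spent punishing | `> 0`             | grid         |
| `c_t` | contribution threshold (resource units)   | `> 0`             | 1            |
| `c_p` | punishment reserve (resource units)       | `0 < c_p <= c_t`  | 0.2          |

The six-node sweep defaults (`c_t = 1`, `c_p = 0.2`, `b = 4`) are chosen so
that the punishment-efficiency grid spans required in-degrees 5 down to 1
*and* the efficiency condition can hold in the fully distributed corner:
with `min(k_in) = max(k_out) = 5` the complete graph carries `K = 30` links
and needs `b > 6 / (6 - 30/m) > 3` at any monitoring efficiency compatible
with a span-of-control of 5, so a public-goods multiplier below ~3 makes the
distributed corner unreachable regardless of the grids.

## Equilibrium checking

`is_nash` verifies, for every node, that neither switching its pure label
nor any partial total contribution on a uniform 21-point grid over
`[0, c_t]` *strictly* increases its own payoff (ties favour the incumbent
strategy, the standard weak-preference convention). Partial payers allocate
with the same priority order and are classified as punishable free-riders
whenever their total falls below the full threshold (or their role is
unaffordable); their partial public-good payment still benefits others. The
grid is a sanity net, not a proof: the deviation payoff is linear in the
contribution level between the classification breakpoints, so its optimum
sits at a pure strategy and 21 points comfortably bracket it.

`brute_force_socially_efficient_nash` enumerates all `2^N` label profiles
(guarded to `N <= 12`), filters to profiles where no unilateral label switch
strictly improves the switcher, and returns the highest group payoff, with
ties broken toward universal contribution and then lexicographically.
Profiles containing an unaffordable contributor role are unrealizable and
skipped. On networks satisfying both degree bounds the socially efficient
Nash profile is uniform (all-contribute or all-free-ride); the test suite
checks this over randomized batteries rather than assuming it, and also
records a counter-example showing the restriction matters (a monitored
reciprocal dyad plus unmonitored bystanders supports a profitable mixed
equilibrium).

The analytic bounds use exact-integer-aware rounding: `ceil` / `floor` are
applied after snapping values within `1e-9` of an integer, because the
incentive condition is a weak inequality at the boundary (an argument of
exactly 2.0 must give a minimum in-degree of 2, not 3). All float
comparisons elsewhere use the same absolute tolerance `1e-9`; budget
identities hold to `1e-12` on rational inputs.

## Sampling socially optimal networks

A spec `(N, d_in, d_out_cap)` demands in-degree exactly `d_in` everywhere,
out-degrees at most `d_out_cap` (additionally clipped to `N - 1`: a simple
digraph admits no more), `K = N * d_in` links, and monitoring concentrated
on `ceil(N d_in / cap)` monitor nodes so pure contributors are maximized.
Monitors are the lowest-indexed nodes; all reported scores are invariant
under relabeling, so this costs no generality. Monitors may monitor other
monitors — pure contributors are an emergent out-degree-0 set, not a caste.

Sampling proceeds per draw:

1. draw the monitors' out-degree composition (positive parts bounded by the
   cap, summing to `K`) uniformly via dynamic-programming counts;
2. match the out-stubs to the `d_in`-regular in-stub multiset by a random
   permutation;
3. repair conflicts (self-loops, parallel links) with random pairwise stub
   swaps accepted when they do not increase the conflict count — a seeded
   local search that converges quickly for sparse specs and deterministically
   reaches the unique solution for forced dense specs such as
   `N = 6, d_in = cap = 5`, where a bare permutation essentially never
   succeeds (acceptance probability `(5!)^12 / 30! ≈ 3e-8`);
4. reject the draw if conflicts remain or the graph is not weakly connected,
   retrying up to 10,000 times before raising a sampling error (a signal of
   a combinatorially tight spec, e.g. all degrees pinned to 1 on four nodes,
   where a third of draws split into two dyads).

The repair step makes the distribution over valid networks near-uniform
rather than exactly uniform; everything the package asserts depends on the
constraint set (which is preserved exactly) and on order statistics of the
hierarchy score, which are stable under this scheme. Weak connectedness is
enforced, matching the connectedness dimension of the hierarchy measures.
All randomness flows through one `numpy` generator, so equal seeds give
identical samples.

## Hierarchy measures

Reachability is the boolean transitive closure (paths of length >= 1) of
the adjacency matrix, computed by repeated squaring. Graph hierarchy treats
pairs as unordered: `H = 1 - (# reciprocally linked pairs)/(# linked
pairs)`, undefined (an error) when no pair is linked. Graph efficiency uses
the full digraph as the maximum, `E = 1 - (K - (N-1)) / ((N-1)^2)`, which
anchors the complete digraph at 0 and any out-tree at 1; it is defined only
for single-component inputs, as is least-upper-boundedness. LUB counts
unordered pairs lacking a common ancestor under reflexive reachability
against the worst case `(N-1)(N-2)/2`; two denominator conventions exist in
the literature, but every in-scope network scores exactly 1, so the choice
is inert here. Connectedness handles any input via weak components. The
composite score is the product `E * H`.

For optimal networks `E` depends only on `(N, d_in)`:
`E = 1 - (N d_in - (N-1)) / (N-1)^2`, which is how graph efficiency rises
predictably with punishment efficiency (through a smaller required
in-degree); `H` varies across samples, e.g. at `N = 6, d_in = 1, cap = 2`
both two-monitor (`H = 10/11`) and three-monitor-cycle (`H = 3/4`)
backbones occur.

## Sweeps and problem sizes

`run_sweep` evaluates an `(m, p)` grid at fixed `(N, b, c_t, c_p)`: each
cell gets its degree bounds, a feasibility verdict (infeasible cells are
where universal free-riding is socially optimal), `n_samples` sampled
optimal networks, the min/median/max of `H` and the composite, and the
median-`H` sample persisted as the representative network. Cell seeds are
spawned deterministically from the sweep seed and the cell index, so the
output CSV is reproducible byte-for-byte.

Library default is 10,000 samples per cell; the test suite and acceptance
script use 400 (sweep) and 10,000 (single-cell sampler contract), sizes at
which the median hierarchy score is already stable to well below the
assertion margins for `N <= 12`. The brute-force battery uses 220 random
(parameter, network) instances over `N` in 3..6.

## Known limitations

- The closed-form lower bound for the hierarchy score of optimal networks
  is not implemented; the sampled minimum serves as its empirical stand-in.
- The sampler is near-uniform, not exactly uniform, over the constraint set;
  exact uniform sampling of degree-constrained connected digraphs would need
  an MCMC switch chain with mixing diagnostics.
- Single-shot, homogeneous agents, exogenous networks: no dynamics of
  network formation, shocks, second-order free-riding invasion, or payoff
  heterogeneity between ranks.
- These are synthetic-game results: passing tests demonstrate internal
  consistency of the model and its analytic conditions, not properties of
  any empirical organization.
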