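# Methods

## The object of study

A football **passing network** is a directed, weighted, spatially embedded
graph: nodes are the eleven players of one team, the weight `w_ij` counts
completed passes from player *i* to player *j*, and each node carries the
mean origin position of the passes it sent.  `passnet` builds two kinds of
network from a time-ordered stream of completed passes:

* the **match-average network**, accumulating every pass of the match, and
* **sliding l-pass networks** (default `l = 50`): the window of the `l`
  most recent passes, advanced one pass at a time and stamped with the
  time of its last pass.  Every sliding network of both teams has the same
  number of nodes *and* links, so differences between them are purely
  structural — the total pass count is factored out.

To keep all networks on exactly eleven nodes across substitutions, each
titular player owns a node "slot" and an incoming substitute inherits the
slot of the player replaced, transitively for chained substitutions.  A
slot never changes owner-index during a match.

## Metric suite

Spatial metrics act on the pass window itself; only pass **origins**
contribute to positions (receiving a pass does not move a node):

* centroid ⟨X⟩, ⟨Y⟩ — mean origin coordinate, field units in [0, 100],
  with x increasing toward the opponent's goal;
* centroid dispersion — population SD of the sending players' distances
  (each player represented by their mean origin) to the centroid.
  Requires ≥ 2 distinct senders; a per-pass variant is available behind a
  flag for sensitivity analysis;
* advance ratio ⟨Δy⟩/⟨Δx⟩ — Σ|y₂−y₁| / Σ|x₂−x₁| over the window.
  Displacements are summed **unsigned**: a signed sum would cancel forward
  against backward passes and could not represent a travelled length.
  The signed variant exists behind a flag.  Undefined (reported as
  missing, never infinity) when Σ|Δx| = 0;
* window time `t_net` — seconds from the first to the last pass of the
  window; the shorter, the faster a team strings `l` passes together.

Topological metrics act on the weight matrix.  The spectral quantities —
weighted clustering C, largest eigenvalue λ₁, algebraic connectivity λ̃₂,
eigenvector centrality — presuppose a symmetric operator, so they use the
symmetrized matrix `A = W + Wᵀ` (total passes exchanged per pair).  Only
the shortest path honours direction, because it is the ball that travels
the directed links:

* **C** — Zhang–Horvath weighted clustering,
  `C_w(i) = Σ_{j≠k} w_ij w_jk w_ik / Σ_{j≠k} w_ij w_ik`, with weights
  rescaled by the maximum entry so C ∈ [0, 1]; mean over the 11 nodes;
  nodes with < 2 weighted neighbours contribute 0.  On a binary graph
  this reduces to the classical unweighted coefficient.
* **d** — average shortest directed path under inverse-weight link
  lengths `l_ij = 1/w_ij` (Dijkstra).  When a 50-pass window is not
  strongly connected, d averages over the reachable ordered pairs only
  and `reachable_fraction` reports the coverage, making the substitution
  visible instead of silently dropping pairs.
* **λ₁** — largest eigenvalue of A ("network strength").  For integer
  counts it obeys `s_max ≥ λ₁ ≥ max(⟨S⟩, √s_max)` with `s_i` the node
  strengths; the bound is asserted in tests.  Note the strength reading
  of `s_max`: the literal "largest single link weight" would violate the
  upper bound already on a uniform complete graph.
* **λ̃₂** — second-smallest eigenvalue of the Laplacian `L̃ = S − A`
  (S = diagonal of strengths); 0 exactly when the team splits into
  disconnected groups.
* **EC** — leading eigenvector of A, taken non-negative (Perron) with
  unit Euclidean norm, so a perfectly uniform team sits at the reference
  point `EC_max = 1/√11 ≈ 0.3015`.  `EC_disp` is the population SD over
  all 11 slots including zero-centrality slots.

Undefined metrics are always explicit NaN, never silent zeros.

## Temporal and season analysis

Per match and team, one metric vector is computed per sliding window
(timestamps strictly increasing).  **Goal-anchored states** take, for
each goal of each match a team plays, the team's last complete window
*strictly* before the goal time ("just before": a pass simultaneous with
the goal is excluded); vectors are classified scored/conceded by who
scored and averaged over the season.  Goals arriving before the team's
first complete window are skipped and counted.

The **season summary** evaluates the match-average network of the focal
team and of each opponent, one row per (match, team); the focal team is
averaged with itself while all opponents pool into a single "rival"
group.  Classical tallies ride along: pass counts, goals, league points
(3/1/0).  Shot counts are accepted as optional external metadata — they
are not derivable from pass events — and the shots column simply appears
when provided.

**Comparison**: per metric, focal per-match values vs pooled rival
per-match values with the two-sided Wilcoxon rank-sum test (exact
enumeration when `n_a + n_b ≤ 12` and tie-free, else normal approximation
with tie correction and no continuity correction; a fully tied pooled
sample returns p = 1).  The family is corrected with step-up FDR,
Benjamini–Hochberg by default and Benjamini–Yekutieli as an option, at
nominal α = 0.01; the reported `alpha_adjusted` is the largest p-value
actually rejected.  The default family is the 13 per-match metrics
(pass count, goals, points, four spatial, six topological), plus shots
when present.  League points enter per match (3/1/0 per match): a season
total is a single number per team and admits no two-sample test.

## Synthetic data generator

The generator emulates the *structure* of league event data, not
football tactics.  Possession strictly alternates; chain lengths are
geometric in `retain_prob` (mean `1/(1−retain_prob)`); inter-pass times
are exponential with mean `60/pass_rate` seconds, and an exponential
turnover gap (mean 5 s) separates possessions.  Players sit at formation
anchors (default 1-4-4-2) with isotropic Gaussian noise (`position_sd`,
default 8 f.u.); receivers are drawn from the sender's row of an
affinity matrix (uniform by default; a "hub" preset concentrates play on
one midfielder).  Each pass's goalward displacement is set to
`|Δy|/advance_bias`, and at a field boundary the whole displacement is
shrunk toward the origin, so the lateral/goalward ratio of every pass —
hence the match advance ratio — equals `advance_bias` exactly up to
floating-point rounding.  After each pass the passing team scores with
probability `goal_hazard_scale · (x₂/100)²` (default scale 0.015,
≈ 1–2 goals per team per 90 minutes): a hazard monotone in the
destination coordinate, which induces the "teams play more advanced
before scoring" signature that the goal-anchored pipeline must recover.
Substitutions are applied at possession boundaries and the emitted event
carries the application time, so "no passes by the outgoing player after
the substitution" holds exactly.

Default study conditions: 90-minute matches; `pass_rate = 12` passes per
possession-minute and `retain_prob = 0.8` give ≈ 450 passes per team per
match — a high-possession league profile.  A 20-team double round-robin
season is 380 matches, 38 per team; per-match seeds derive
deterministically from the season seed.

What the generator does **not** emulate: tactics, off-ball movement,
fatigue, in-match parameter drift, turnover geometry (turnovers are
implicit chain ends; only completed passes are emitted, as in the
completed-pass event feeds this package targets).  Tests passing on
synthetic data therefore validate the *pipeline arithmetic and
statistics*, not claims about real teams.

### Known numerical effects

* Origins are clipped (not resampled) at the field boundary; with
  `position_sd ≪ 50` the effect is small but measurable: a planted
  centroid offset of 8 f.u. with forward anchors near x = 83 is
  recovered with a systematic deficit of ≈ 0.1 f.u. (clipping pulls
  boundary-adjacent means inward).  The recovery test carries a 0.15 f.u.
  allowance for this documented effect on top of its 3-SE Monte-Carlo
  band.
* The per-pass-exact advance ratio makes per-match ratios identical up
  to ~1 ulp; knife-edge ties like this can flip the rank-sum test
  between its exact and asymptotic paths when values pass through text
  serialization.  Decisions are unaffected.

## Verification design

Each non-trivial operation is checked against an independent oracle that
shares no code with the implementation path: a literal triple-loop for
weighted clustering (exhaustive over all symmetric 4-node graphs with
weights {0..3}, sampled at 5 nodes), brute-force simple-path enumeration
for shortest paths (exhaustive over all 3-node digraphs with weights
{0..2}, sampled at 6 nodes), an independent dense eigensolver and a
shifted power iteration for the spectral metrics, full label-assignment
enumeration for exact rank-sum p-values, and a direct evaluation of the
step-up rule for FDR.  Closed-form limits (complete-graph λ₁ = 10w and
λ̃₂ = 11w, star-graph Perron vector, uniform centrality 1/√11) pin the
conventions.  Property tests (seeded/derandomised) cover translation
equivariance of the spatial metrics, scale covariance of the topology
suite under `W → kW` (C and centrality invariant, λ's scale by k, d by
1/k), sliding-window incremental-vs-rebuild equality, and λ̃₂ = 0 iff
disconnected against a union-find oracle.

Statistical calibration runs at stated sizes: 100 matches for parameter
recovery (3 Monte-Carlo SEs), 38 matches for planted-effect detection,
and 200 replicate 4-team seasons of 45-minute matches for the null FDR
calibration (shorter matches keep the replicate count high at fixed
cost; the test checks the family-wise rejection rate stays within
3·√(α(1−α)/200) of α = 0.01).

## Limitations

* The slot-inheritance rule needs explicit substitution records; they
  are not inferred from roster changes in the pass stream.
* `d` on sparse windows is a partial average; always read it together
  with `reachable_fraction`.
* The FDR-adjusted threshold depends on the whole p-value family, so
  adding or removing metrics changes individual decisions; the family is
  therefore explicit and configurable.
* Real event feeds contain measurement error in coordinates and
  timestamps that the generator does not model.
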