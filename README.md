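# passnet

Temporal network analysis of football passing data.

A team's passing behaviour can be read as a directed, weighted, spatially
embedded network: nodes are the eleven players, the weight `w_ij` counts
completed passes from player *i* to player *j*, and each node sits at the
mean position its passes were sent from.  `passnet` turns a time-ordered
stream of pass events into such networks and tracks how their structure
evolves during a match:

* **match-average networks** — all passes of a match in one graph;
* **sliding 50-pass networks** — the window of the 50 most recent passes,
  advanced one pass at a time, which removes the total pass count from
  the comparison and exposes the temporal fluctuations of the structure;
* a **metric suite** per network: centroid coordinates ⟨X⟩, ⟨Y⟩ and
  dispersion, advance ratio ⟨Δy⟩/⟨Δx⟩, window construction time,
  weighted clustering C, average shortest-path length d (Dijkstra on
  inverse-weight lengths `l_ij = 1/w_ij`), largest adjacency eigenvalue
  λ₁, algebraic connectivity λ̃₂, and eigenvector-centrality maximum and
  dispersion;
* **goal-anchored states** — the last complete window strictly before
  each goal, classified by whether the team scored or conceded;
* a **focal-team season comparison** — per-match metrics of one team vs
  the pooled metrics of its opponents, tested with the two-sided
  Wilcoxon rank-sum test under Benjamini–Hochberg FDR control;
* a **synthetic match generator** with controllable possession share,
  pass rate, formation geometry, receiver preferences, advance bias and
  goal hazard, so the entire pipeline is testable and calibratable
  without proprietary event data.

Substitutions are handled with a slot-inheritance rule — an incoming
player occupies the node of the player replaced — so every network has
exactly eleven nodes throughout.

It is aimed at sports-analytics researchers and practitioners working
with completed-pass event feeds (times in seconds, pitch coordinates
normalised to [0, 100] "field units" on both axes).

See `docs/methods.md` for the precise definitions, conventions and
verification design.

## Worked example

```python
from passnet import (SimulationConfig, TeamProfile, build_average_network,
                     default_subs, evaluate_network, generate_match,
                     hub_affinity, metric_timeseries)

focal = TeamProfile(name="Focal", retain_prob=0.85, advance_bias=1.4,
                    receiver_affinity=hub_affinity(),
                    sub_schedule=default_subs("Focal"))
rival = TeamProfile(name="Rival", retain_prob=2 / 3)
match = generate_match(SimulationConfig(team_a=focal, team_b=rival), seed=1)

net = build_average_network(match, "Focal")
mv = evaluate_network(net)
print(f"L={mv.L}  <X>={mv.X_mean:.2f}  adv={mv.advance_ratio:.3f}  "
      f"C={mv.C:.3f}  d={mv.d:.3f}  lam1={mv.lambda1:.1f}  "
      f"lam2={mv.lambda2_alg:.1f}  EC_max={mv.EC_max:.3f}")

series = metric_timeseries(match, "Focal", l=50)
print("windows:", len(series.samples))
```

prints

```
L=574  <X>=43.07  adv=1.400  C=0.501  d=0.115  lam1=131.0  lam2=72.4  EC_max=0.618
windows: 525
```

Reading: the focal team completed 574 passes (`L`), its network centroid
sat at x ≈ 43 field units, and its advance ratio of 1.400 recovers the
configured lateral-play bias exactly.  Dense passing makes links
topologically short (`d` ≈ 0.115 inverse-pass units) and the network
strong (λ₁ = 131, λ̃₂ = 72).  The playmaker hub pushes the maximum
eigenvector centrality to 0.618, well above the uniform-team reference
1/√11 ≈ 0.302.  The match yields 525 overlapping 50-pass windows, each
scored with the same metric suite to give the team's metric time series.

## Command line

The same pipeline is exposed as CLI verbs, writing plain CSV tables plus
a JSON manifest (seed, config, skip counters) per output directory:

```bash
passnet simulate --out season/ --seed 7 --n-teams 20
passnet average --input season/ --focal-team T01 --alpha 0.01 --out avg/
passnet timeseries --input season/T01-vs-T02.csv --l 50 --out ts/
passnet goals --input season/ --l 50 --out goals/
passnet compare --per-match avg/per_match.csv --out cmp/
```

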