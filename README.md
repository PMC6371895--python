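# streamclass

Multi-layered habitat classification for stream-reach networks.

Stream ecosystems are organized by a physical template: how much water a
reach carries, how steep it is, how its flow and temperature vary through
the year, how it sits within the branching network, and how freely it can
interact with its floodplain. `streamclass` assigns every reach of an
NHDPlus-style hydrography (a reach attribute table plus a "from-to"
topology table keyed by COMID) to classes in six such habitat layers:

| Layer | Classes | Method |
|---|---|---|
| Size | HW, SC, LC, SR, MR, MS, LR, GR | discharge bins; thresholds are mid-points between per-Strahler-order median discharges |
| Gradient | VL, L, M, MH, H, S | fixed Rosgen-style slope bins |
| Hydrology | nested W2, W4, W8, ... | Ward minimum-variance clustering of gaged flow signatures, extrapolated to reaches by a random forest with vote-fraction probabilities |
| Temperature | VC, CD, CC, CL, CW, W | reference-site screening → regression forest for mean July–August temperature → fixed or Fisher–Jenks thresholds |
| Network bifurcation | junction codes (`2.12`, `5.511`, `1_0`, ...) + divergence classes D1/D2/DU/D | Strahler-order combinations at each reach's upstream junction; split-reach correction via ecological units |
| Valley confinement | unconfined / moderately confined / confined | flood-height (5× bankfull depth) valley-bottom delineation vs. river width, rule engine |

It is written for freshwater ecologists and ecoinformaticians who need
reach-resolution classes for conservation planning, species distribution
modeling, or reference-condition screening — and for anyone who wants to
exercise, extend, or audit such a classification without downloading
continental hydrography: a seeded synthetic generator produces dendritic
networks with divergences, map-boundary splits, drainage-area scaling laws
(Q = cA^b, S = kA^(−θ)), clustered gage signatures, and valley-bottom
geometry, all with retained ground truth.

## The core statistics

* **Junction coding.** Each reach's upstream Strahler orders form its
  bifurcation class: an order-1 and an order-2 tributary feeding an
  order-2 reach code as `2.12`; three or more contributors lead with the
  mainstem order (`5.511`); headwaters and mid-channel splits are
  `<order>_0`. Divergent channels are main (D1) or secondary (D2);
  rejoins are DU; junctions whose order arithmetic contradicts an
  unflagged Strahler combination get the generic divergence class D.
* **Ward + forest extrapolation.** Gage-level class solutions are nested
  cuts of one Ward dendrogram (within-cluster SSE from merge heights via
  ΔSSE = h²/2); reach-level class probabilities are the fraction of trees
  voting for each class, with 1/k as the chance reference.
* **Fisher–Jenks breaks.** Exact dynamic program minimizing within-class
  squared deviation over contiguous partitions, with goodness-of-variance
  fit and its absolute-deviation analog (tabular accuracy) used to pick a
  parsimonious class count.
* **Confinement rules.** With `cov` the fraction of reach length overlain
  by valley bottom and `r` the valley-to-river width ratio:
  unconfined iff `cov ≥ 0.5 ∧ r ≥ 4`; moderately confined iff
  `0.25 ≤ cov < 0.5 ∧ r ≥ 4` or `cov ≥ 0.5 ∧ 2 ≤ r < 4`; else confined.
  Fully inundated reaches are unclassified.

## Worked example

The numbered drivers under `analysis/` run the whole study on a generated
500-reach network (seed 1234) and write tables under `results/`:

```sh
python analysis/01_generate_network.py
python analysis/02_size_gradient.py
python analysis/03_bifurcation.py
python analysis/04_hydrology_classes.py
```

`03_bifurcation.py` prints:

```
28 distinct bifurcation classes
most frequent: {'1_0': 248, '2_0': 53, '2.11': 44, '3_0': 35, '2.12': 20, ...}
divergence classes: {'none': 452, 'DU': 15, 'D1': 15, 'D2': 15, 'D': 3}
non-sensical junctions flagged: 2
split-reach correction rewrote 5 reach classes
```

— half the network is first-order reaches without an upstream confluence
(`1_0`), divergences appear as matched D1/D2 channel pairs with their DU
rejoins, and the deliberately unflagged divergences surface as the generic
class D. `04_hydrology_classes.py` prints the accuracy/probability
diagnostics:

```
solution  k  n_obs  oob_error_pct  accuracy_pct  median_prob  expected_prob
      W2  2    200            2.0          98.0        0.970           0.50
      W4  4    200            5.0          95.0        0.960           0.25
      W8  8    200           40.5          59.5        0.706           0.13
```

— out-of-bag error grows as the dendrogram is cut finer than the true
4-cluster structure, while the median vote fraction of the predominant
class stays well above the 1/k chance level in every solution.

The same computation is available as a pipeline (`streamclass all --seed 7
--outdir out/`, or `run_pipeline(config)`), which writes one CSV per layer
plus a manifest; reruns with the same config are byte-identical.

## Layout

* `src/streamclass/` — the library: `network` (data model, Strahler,
  accumulation), `synth` (generators), `size_gradient`, `bifurcation`,
  `regimes`, `breaks`, `confinement`, `pipeline`, `cli`.
* `analysis/` — numbered narrative drivers.
* `tests/` — unit, property, and acceptance suites (with brute-force
  oracles for Jenks, Ward, junction consistency, and the confinement rules).
* `docs/methods.md` — model assumptions, parameter defaults, numerical
  conventions, and known limitations.
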