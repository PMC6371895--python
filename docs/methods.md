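# Methods

This note records the models behind each classification layer, the
parameters that matter, the conventions fixed where the underlying
literature is silent, and what the synthetic generator does and does not
emulate.

## Network model

A network is a reach attribute table plus a from-to edge list (upstream →
downstream). Topology is purely tabular; no geometry is stored, because
every layer needs only attributes and connectivity. Discharge is held in
m³/s internally (thresholds are defined in m³/s); cfs inputs are converted
at ingest (1 cfs = 0.0283168 m³/s).

**Strahler orders.** Headwaters are order 1; at a junction the order
increments only when two or more *independent* tributaries share the
maximal order. Channels flagged as secondary (D2) divergences are excluded
from that count — a stream rejoining its own divergence is not a new
tributary — but still bound the maximum, so secondary channels inherit the
parent order. Source hydrography assigns divergent channels an order
without documenting the rule; inheritance is our fixed, documented
stand-in.

**Accumulation.** Attribute accumulation routes 100% of the parent's value
down the main (D1) channel at divergences to avoid double counting;
`secondary_fraction` makes the split configurable. Non-secondary children
share whatever the secondaries do not take.

## Size and gradient

Size thresholds are mid-points between median discharges of consecutive
Strahler orders, derived in m³/s; the shipped defaults are the national
thresholds (HW < 0.057 ≤ SC < 0.283 ≤ LC < 1.133 ≤ SR < 5.663 ≤ MR <
22.65 ≤ MS < 70.79 ≤ LR < 283.2 ≤ GR). Gradient uses the Rosgen-style
breaks 0.001 / 0.005 / 0.02 / 0.04 / 0.1 (rise/run). All bins — size,
gradient, and temperature — are **lower-inclusive, upper-exclusive**, the
last bin open above; printed threshold tables show touching ranges without
stating inclusivity, so one convention is fixed everywhere (slope exactly
0.02 is MH, discharge exactly 0.057 is SC, 24 °C is W). Missing values
yield an explicit `unclassified` label rather than an error or a dropped
row. Non-monotone order medians abort derivation with the offending orders
named: they mean discharge does not scale with the network.

## Network bifurcation

Junction codes are a pure function of (downstream order, upstream orders).
Conventions, fixed because the two canonical examples imply different sort
directions:

* zero or one upstream reach → `<order>_0` (mid-channel splits look like
  ordinary continuation reaches until split correction runs);
* exactly two tributaries → digits ascending (`2.12`);
* three or four → the order matching the downstream reach leads, the
  remainder descends (`5.511`); `sort_mode` can force either direction;
* more than four contributors keep the largest four (the cap is
  documented in the source material; the selection rule is ours);
* orders ≥ 10 render as hyphen-joined tokens (`12.10-3`) since digit
  concatenation is ambiguous there; the token list stays canonical.

Rendering is injective for orders ≤ 9 (enumeration-tested to order 6, four
tributaries).

**Divergences.** D1/D2 come from the channel flags. DU marks reaches where
two or more channels descending from one divergence re-merge; membership is
traced by propagating (divergence parent, channel head) pairs down
single-channel paths. A rejoin of only one divergent channel does not
qualify (the requires-two rule is our reading of "confluences of channel
divergences"). A junction is *non-sensical* — generic class D — when ≥ 2
unflagged reaches merge and the downstream order contradicts the Strahler
combination of the upstream orders: the signature of a divergence the
hydrography failed to code. D reaches keep D as their bifurcation class
too, since their order arithmetic is untrustworthy.

**Split correction.** Reaches sharing an ecological unit id (map-boundary
splits) all inherit the bifurcation and divergence class of the unit's
upstream-most member. Units that are not a single directed chain are
skipped with a warning. The operation is idempotent.

## Hydrologic regimes

Gage flow signatures (component scores standing in for PCA-reduced
hydrologic statistics) are clustered with Ward's minimum-variance method
(`scipy` linkage). Cuts of one dendrogram at several k are nested by
construction; labels are renumbered 1..k by first appearance, and argmax
label ties break toward the lowest class index. Merge ties follow scipy's
deterministic order. Within-cluster SSE at any k is recovered from merge
heights via ΔSSE = h²/2, which feeds the elbow (second-difference of SSE
vs k) candidate list; candidates are advisory — the configured k list is
authoritative, mirroring practice where the dendrogram is inspected
visually. Greedy agglomeration is not globally optimal in general; on
separated data the cut coincides with the exhaustive minimum-SSE
partition, and that is the regime the equivalence test exercises.

**Imputation** is chained predictive mean matching: each incomplete column
is regressed linearly on the others; a missing entry takes the observed
value of one of `k_donors = 5` nearest-predicted neighbors, drawn from the
seeded stream; columns are cycled `max_iter = 5` times. Columns ≥ 50%
missing are refused. Missingness in the generator is MCAR (about 2% by
default, matching the scale of gaps in assembled landscape predictors).

**Extrapolation** uses a 500-tree random forest (seed mandatory, routed
through named substreams). OOB misclassification is the internal accuracy
estimate; accuracy is reported as its exact complement. Class-membership
probabilities are *tree vote fractions*, not averaged leaf probabilities;
they sum to one and their median for the predominant class is compared to
the chance level 1/k. Expected probabilities are reported half-up to two
decimals (1/8 → 0.13), the convention of printed tables. Feature
importances are min-max normalized so the most informative feature scores
1 (the published caption prints the inverted formula, contradicted by its
own narrative; the standard direction is used here).

## Temperature

Reference screening keeps sites with disturbance "very low" or "low",
degree of regulation strictly below 4%, record window within [1995, 2015]
inclusive on both ends, and at least 60 consecutive July–August days;
sites missing any attribute are excluded with a logged reason. The summer
temperature model is a 500-tree regression forest; Qwsa (discharge per
unit drainage area) is barred from its features by an explicit guard,
because a size-standardized flow ratio would leak river size into a model
whose target already varies with size. Classes come either from the fixed
thresholds 10 / 15 / 18 / 21 / 24 °C (six classes VC…W) or from a
Fisher–Jenks partition of the predicted temperatures; both paths ship
because the fixed table and the data-driven parsimony analysis are
complementary framings.

## Fisher–Jenks

The exact Fisher dynamic program minimizes total within-class squared
deviation over contiguous partitions of the sorted sample (O(kn²),
vectorized inner loop, ties toward the smallest boundary index). GVF = 1 −
SDCM/SDAM; *tabular accuracy* is not defined in the source literature, so
the absolute-deviation analog of GVF — a standard map-classification
diagnostic — is adopted and named as such. Constant data is a perfect fit
by definition. Exported breaks are each class's maximum (right-closed
representation). `select_parsimonious_k` returns the smallest k whose
successor improves neither diagnostic by `plateau_delta = 0.02`, a default
chosen to flag the knee on well-separated synthetic mixtures; no plateau
returns the range maximum with a warning.

## Valley confinement

Flood height is `multiplier × a·A^b·P^c` with A drainage area (km²) and P
mean annual precipitation (mm); the multiplier defaults to 5× bankfull
depth. The bankfull coefficients are region-specific and config-required;
the shipped (a, b, c) = (0.04, 0.35, 0.25) are demonstration values giving
~1 m bankfull depth at A = 100 km², P = 1000 mm. Delineation grows a
4-connected region from each stream cell, admitting cells no higher than
that seed's elevation plus the flood height, excluding waterbody cells;
valley-bottom width is area/length (VBA/VBL — an area-based mean, chosen
over a maximum because the bookkeeping is in area and length totals), and
coverage is the fraction of stream cells whose channel carries valley
bottom. On a V-valley of side slope s the delineated half-width converges
to h/s within one cell.

River width is modeled on log10(width): observed widths span orders of
magnitude and a squared-error loss is only coherent multiplicatively (an
MSE of ~0.13 against widths from <1 to >10⁴ m implies a log scale);
back-transformation keeps predictions strictly positive. Fewer than 30
observations are refused.

Rule boundaries: "at least four times" vs ">4×" conflict in the source
phrasing; ≥ is adopted for both width-ratio clauses (r ≥ 4), the moderate
band is 2 ≤ r < 4, and coverage boundaries 0.25 and 0.5 are inclusive on
their lower side. The engine is enumeration-tested against an independent
restatement on a 10⁴-point grid including every boundary value.

## Synthetic generator

The generator emulates the *structure* the classification consumes, not
river physics: a tip-branching growth process (topology and scaling are
what matter, not planform geometry), drainage-area power laws Q = c·A^b·ε
(c = 0.012, b = 0.9, lognormal ε with sd 0.1 — plausible humid-basin
scaling) and S = k·A^(−θ) (k = 0.08, θ = 0.45, spanning all six gradient
classes across four decades of area), lognormal local catchment areas
(median 2 km²), divergence diamonds at 3% of reaches, map-boundary splits
at 3%, and 1% *unflagged* diamonds whose orders are computed while the
flags are known and then erased — reproducing exactly the inconsistently
coded junctions the generic class D exists for. Gage signatures are a
k-component Gaussian mixture with centers `separation` within-cluster
standard deviations apart (defaults k = 4, separation 6, n_sites 200);
reach covariates carry the same class structure so extrapolation is
learnable. Temperature is a known smooth function of elevation, latitude
and log discharge plus Gaussian noise (sd 1 °C); screening attributes are
drawn from independent mixtures (50% low/very-low disturbance, DOR uniform
0–10%, records 1995–2014, 50–90 consecutive days) so the expected kept
fraction is computable by enumeration. Valley inputs come from a
four-component mixture guaranteeing every confinement class occurs, with
hydraulic-geometry widths w = 7.2·Q^0.5.

Defaults of 500 reaches and 200–400 sites keep the full suite and the
drivers at desk scale (the whole test suite runs in well under a minute).
All generators are bit-identical under a fixed seed; every consumer draws
from a named substream of one global seed, so toggling a pipeline layer
never perturbs another layer's randomness.

**What passing tests do not show:** real hydrography has spatial
autocorrelation, regionally varying scaling laws, non-MCAR missingness,
braided channels that defeat accumulation, and gage records with serial
dependence — none of which the generator produces. Recovery results
(ARI ≥ 0.9, OOB ≤ 5%) characterize the machinery under clean separation,
not expected performance on continental data, where misclassification
rates of 5–35% are the realistic range.

## Known limitations

* The DEM path handles in-memory grids and plain-text rasters only; no
  GeoTIFF/geodatabase I/O.
* DU detection requires two or more rejoining channels of the same
  divergence; single-channel rejoins stay unlabeled.
* Ward/exhaustive equivalence and the elbow selector are reliable only
  under clear cluster separation.
* The bankfull-depth coefficients are placeholders for regional
  calibration; confinement classes from the demonstration defaults are
  illustrative.
* The soft (Gaussian-mixture) hydrologic classification is consumed as an
  externally supplied label column when present, not re-derived; Ward is
  the implemented path.
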