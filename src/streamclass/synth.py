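"""Seeded synthetic generators standing in for NHDPlus/StreamCat/USGS data.

The generators produce dendritic reach networks with divergences and
map-boundary splits, drainage-area scaling laws for discharge and slope,
clustered gage signatures, temperature sites with screening attributes, and
valley-bottom inputs.  Ground truth (labels, law coefficients, analytic
widths) is retained so recovery tests can close the loop.

Topology is grown by a tip-branching stochastic process: only topology and
scaling structure matter to the downstream classification layers, not
planform geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .network import ReachNetwork, accumulate_upstream, compute_strahler_order
from .seeds import substream

GagePanel = pd.DataFrame  # site-by-feature matrix; see generate_gage_panel

DISTURBANCE_LEVELS = ("very low", "low", "moderate", "high", "very high")

#: Default categorical mixture for site disturbance scores (50% reference pool).
DISTURBANCE_PROBS = (0.25, 0.25, 0.2, 0.2, 0.1)
#: DOR is uniform on [0, DOR_MAX) percent; the < 4% screen keeps 4/DOR_MAX.
DOR_MAX = 10.0
#: July-August consecutive-day counts, uniform on {DAYS_LO..DAYS_HI}.
DAYS_LO, DAYS_HI = 50, 90


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic network generator.

    Scaling laws: discharge Q = c * A^b * eps with eps lognormal(0, noise_sd),
    slope S = k * A^(-theta), A the accumulated drainage area in km^2.
    """

    seed: int
    n_reaches: int = 500
    branch_prob: float = 0.4
    divergence_rate: float = 0.03
    split_rate: float = 0.03
    unflagged_divergence_rate: float = 0.01
    discharge_law: tuple[float, float] = (0.012, 0.9)  # (c, b)
    discharge_noise_sd: float = 0.1
    slope_law: tuple[float, float] = (0.08, 0.45)  # (k, theta)
    local_area_km2: float = 2.0  # median local catchment area

    def __post_init__(self) -> None:
        if self.n_reaches < 1:
            raise ConfigError("n_reaches must be >= 1")
        for name in ("branch_prob", "divergence_rate", "split_rate",
                     "unflagged_divergence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.discharge_law[0] <= 0 or self.slope_law[0] <= 0:
            raise ConfigError("scaling-law leading coefficients must be > 0")


# ---------------------------------------------------------------------------
# Network topology
# ---------------------------------------------------------------------------

def generate_dendritic_network(config: GeneratorConfig) -> ReachNetwork:
    """Grow a reach network with known Strahler orders and divergence flags.

    Growth starts from the outlet and extends upstream; each step either
    lengthens a tip (one new upstream reach) or, with probability
    ``branch_prob``, bifurcates it (two).  Divergences are then inserted as
    diamonds around existing edges: parent -> {main, secondary} -> rejoin.
    A fraction of diamonds is left unflagged after orders are computed,
    reproducing the inconsistently-coded junctions real hydrography carries.
    Splits insert a mid-channel reach sharing an ecological unit id with its
    upstream neighbour, mimicking quadrangle map-boundary artifacts.
    """
    rng = substream(config.seed, "network")
    # Insertions (diamonds add 2 reaches, splits 1) count toward n_reaches.
    n_div = int(round(config.divergence_rate * config.n_reaches))
    n_unflagged = int(round(config.unflagged_divergence_rate * config.n_reaches))
    n_split = int(round(config.split_rate * config.n_reaches))
    n_tree = max(1, config.n_reaches - 2 * (n_div + n_unflagged) - n_split)
    next_id = 1001
    outlet = next_id
    next_id += 1
    comids = [outlet]
    edges: list[tuple[int, int]] = []
    flags: dict[int, str] = {outlet: "none"}
    tips = [outlet]
    while len(comids) < n_tree:
        tip = tips.pop(int(rng.integers(len(tips))))
        room = n_tree - len(comids)
        n_new = 2 if (room >= 2 and rng.random() < config.branch_prob) else 1
        for _ in range(n_new):
            comids.append(next_id)
            flags[next_id] = "none"
            edges.append((next_id, tip))
            tips.append(next_id)
            next_id += 1

    # Diamonds (flagged + unflagged) around distinct tree edges.
    n_total = min(n_div + n_unflagged, len(edges))
    unflag_later: list[int] = []
    if n_total > 0:
        picks = rng.choice(len(edges), size=n_total, replace=False)
        for j, idx in enumerate(sorted(int(i) for i in picks), start=0):
            parent, down = edges[idx]
            main, sec = next_id, next_id + 1
            next_id += 2
            comids += [main, sec]
            flags[main], flags[sec] = "main", "secondary"
            edges[idx] = (parent, main)
            edges += [(main, down), (parent, sec), (sec, down)]
            if j >= n_div:
                unflag_later += [main, sec]

    eco_unit: dict[int, str] = {}
    if n_split > 0:
        # Split single-downstream, unflagged reaches not already in a unit.
        down_count: dict[int, int] = {c: 0 for c in comids}
        for u, _ in edges:
            down_count[u] += 1
        eligible = [c for c in comids
                    if down_count[c] == 1 and flags[c] == "none"]
        picks = rng.choice(len(eligible), size=min(n_split, len(eligible)),
                           replace=False)
        for idx in sorted(int(i) for i in picks):
            upper = eligible[idx]
            eidx = next(i for i, (u, _) in enumerate(edges) if u == upper)
            _, down = edges[eidx]
            lower = next_id
            next_id += 1
            comids.append(lower)
            flags[lower] = "none"
            edges[eidx] = (upper, lower)
            edges.append((lower, down))
            eco_unit[upper] = eco_unit[lower] = f"EU{upper}"

    rows = pd.DataFrame({
        "comid": comids,
        "strahler_order": 0,
        "length_km": 1.0,
        "slope": 0.0,
        "mean_annual_q": 0.0,
        "divergence_flag": [flags[c] for c in comids],
        "eco_unit_id": [eco_unit.get(c) for c in comids],
        "inundated_fraction": 0.0,
    })
    lognorm = rng.lognormal(np.log(config.local_area_km2), 0.5, len(comids))
    rows["local_area_km2"] = lognorm
    net = ReachNetwork(rows, edges)
    area = accumulate_upstream(net, "local_area_km2")
    net.reaches["drainage_area_km2"] = net.reaches["comid"].map(area)
    order = compute_strahler_order(net)  # flags still set on every diamond
    net.reaches["strahler_order"] = net.reaches["comid"].map(order)
    if unflag_later:
        mask = net.reaches["comid"].isin(unflag_later)
        net.reaches.loc[mask, "divergence_flag"] = "none"
        net._build_index()
    net.meta["generator_config"] = config
    return net


# ---------------------------------------------------------------------------
# Physical attributes
# ---------------------------------------------------------------------------

def attach_physical_attributes(
    net: ReachNetwork, config: GeneratorConfig
) -> ReachNetwork:
    """Attach discharge, slope, lengths and emulated landscape predictors.

    Discharge and slope follow the configured drainage-area power laws; the
    landscape predictors (elevation, latitude, precipitation, temperature,
    base-flow index) are drawn with mild structure so extrapolation models
    have signal to work with.  Ground-truth law parameters are retained in
    ``net.meta["true_laws"]``.
    """
    rng = substream(config.seed, "attributes")
    A = net.reaches["drainage_area_km2"].to_numpy(float)
    c, b = config.discharge_law
    eps = np.exp(rng.normal(0.0, config.discharge_noise_sd, len(A))) \
        if config.discharge_noise_sd > 0 else np.ones(len(A))
    net.reaches["mean_annual_q"] = c * A**b * eps
    k, theta = config.slope_law
    net.reaches["slope"] = k * A**(-theta)
    net.reaches["length_km"] = rng.lognormal(np.log(1.5), 0.4, len(A))

    lat = rng.uniform(25.0, 49.0, len(A))
    elev = np.clip(2500.0 - 400.0 * np.log10(A + 1.0)
                   + rng.normal(0.0, 120.0, len(A)), 0.0, None)
    net.reaches["lat"] = lat
    net.reaches["elev_ws"] = elev
    net.reaches["precip_ws"] = rng.uniform(250.0, 2000.0, len(A))
    net.reaches["tmean_ws"] = 28.0 - 0.5 * (lat - 25.0) + rng.normal(0, 1.5, len(A))
    net.reaches["bfi_ws"] = rng.uniform(10.0, 90.0, len(A))
    net.reaches["qwsa"] = net.reaches["mean_annual_q"] / A
    net.meta["true_laws"] = {
        "discharge_law": config.discharge_law,
        "discharge_noise_sd": config.discharge_noise_sd,
        "slope_law": config.slope_law,
    }
    return net


# ---------------------------------------------------------------------------
# Gage panels (hydrologic regime signatures)
# ---------------------------------------------------------------------------

def generate_gage_panel(
    net: ReachNetwork,
    n_sites: int = 200,
    k_clusters: int = 4,
    separation: float = 6.0,
    missing_frac: float = 0.0,
    seed: int = 0,
    n_scores: int = 13,
) -> GagePanel:
    """Emulate gaged flow-regime signatures with known class structure.

    Every reach receives a latent regime class and class-informative
    covariates ``hydro_cov_*`` (written onto ``net.reaches`` along with
    ``true_hydro_class``); gaged sites sample reaches and carry ``n_scores``
    component scores drawn from a Gaussian mixture whose centers sit
    ``separation`` within-cluster standard deviations apart.  A
    ``missing_frac`` share of score entries is blanked completely at random.
    """
    if k_clusters < 2:
        raise ConfigError("k_clusters must be >= 2")
    if n_sites > len(net):
        raise ConfigError("n_sites exceeds reach count")
    rng = substream(seed, "gage-panel")
    n_reach = len(net)
    reach_class = rng.integers(1, k_clusters + 1, n_reach)
    # Simplex-style centers: pairwise distance exactly `separation`.
    cov_centers = (separation / np.sqrt(2.0)) * np.eye(k_clusters)
    covs = cov_centers[reach_class - 1] + rng.normal(0, 1.0, (n_reach, k_clusters))
    net.reaches["true_hydro_class"] = reach_class
    for j in range(k_clusters):
        net.reaches[f"hydro_cov_{j + 1}"] = covs[:, j]

    idx = rng.choice(n_reach, size=n_sites, replace=False)
    site_class = reach_class[idx]
    centers = np.zeros((k_clusters, n_scores))
    centers[:, :k_clusters] = cov_centers
    scores = centers[site_class - 1] + rng.normal(0, 1.0, (n_sites, n_scores))
    if missing_frac > 0:
        mask = rng.random(scores.shape) < missing_frac
        scores[mask] = np.nan

    panel = pd.DataFrame(scores, columns=[f"pc_{i + 1}" for i in range(n_scores)])
    panel.insert(0, "site_id", [f"G{i:04d}" for i in range(n_sites)])
    panel.insert(1, "comid", net.reaches["comid"].to_numpy()[idx])
    panel["true_label"] = site_class
    _draw_screening_attributes(panel, rng)
    panel.attrs["score_columns"] = [f"pc_{i + 1}" for i in range(n_scores)]
    panel.attrs["k_true"] = k_clusters
    return panel


def _draw_screening_attributes(panel: pd.DataFrame, rng: np.random.Generator) -> None:
    n = len(panel)
    panel["disturbance"] = rng.choice(DISTURBANCE_LEVELS, size=n,
                                      p=DISTURBANCE_PROBS)
    panel["dor_percent"] = rng.uniform(0.0, DOR_MAX, n)
    panel["rec_start"] = 1995 + rng.integers(0, 15, n)  # 1995..2009
    panel["rec_end"] = panel["rec_start"] + 1 + rng.integers(0, 5, n)  # <=2014
    panel["jul_aug_consec_days"] = rng.integers(DAYS_LO, DAYS_HI + 1, n)


def expected_reference_fraction() -> float:
    """Expected kept fraction under the default screening-attribute mixtures,
    by direct enumeration of the screening rules (independent draws)."""
    p_dist = DISTURBANCE_PROBS[0] + DISTURBANCE_PROBS[1]
    p_dor = min(4.0, DOR_MAX) / DOR_MAX
    # record windows: enumerate the discrete (start, duration) grid
    windows = [(s, s + d) for s in range(1995, 2010) for d in range(1, 6)]
    p_window = sum(1995 <= s and e <= 2015 for s, e in windows) / len(windows)
    days = range(DAYS_LO, DAYS_HI + 1)
    p_days = sum(d >= 60 for d in days) / len(days)
    return p_dist * p_dor * p_window * p_days


# ---------------------------------------------------------------------------
# Temperature sites
# ---------------------------------------------------------------------------

#: True July-August temperature model: intercept + coefficients on
#: (elev_ws [m], lat [deg], log10(Q + 0.01) [m^3/s]).
TEMP_COEFS = {"intercept": 34.0, "elev_ws": -0.004, "lat": -0.35, "log_q": 0.8}


def true_july_august_temp(net: ReachNetwork) -> np.ndarray:
    """Noise-free reach temperature from the generator's smooth model."""
    r = net.reaches
    return (TEMP_COEFS["intercept"]
            + TEMP_COEFS["elev_ws"] * r["elev_ws"].to_numpy(float)
            + TEMP_COEFS["lat"] * (r["lat"].to_numpy(float) - 25.0)
            + TEMP_COEFS["log_q"]
            * np.log10(r["mean_annual_q"].to_numpy(float) + 0.01))


def generate_temperature_sites(
    net: ReachNetwork, n_sites: int = 200, noise_sd: float = 1.0, seed: int = 0
) -> GagePanel:
    """Emulate summer water-temperature monitoring sites.

    Temperature is a known smooth function of reach covariates (elevation,
    latitude, discharge) plus Gaussian noise; disturbance scores, degree of
    regulation, and record windows are drawn from mixtures that leave the
    reference screen with both keeps and rejects.
    """
    if n_sites < 1:
        raise ConfigError("n_sites must be >= 1")
    rng = substream(seed, "temperature-sites")
    n_sites = min(n_sites, len(net))
    idx = rng.choice(len(net), size=n_sites, replace=False)
    true_temp = true_july_august_temp(net)[idx]
    panel = pd.DataFrame({
        "site_id": [f"T{i:04d}" for i in range(n_sites)],
        "comid": net.reaches["comid"].to_numpy()[idx],
        "true_temp": true_temp,
        "july_august_temp": true_temp + rng.normal(0.0, noise_sd, n_sites),
    })
    for col in ("elev_ws", "lat", "mean_annual_q", "qwsa"):
        panel[col] = net.reaches[col].to_numpy(float)[idx]
    _draw_screening_attributes(panel, rng)
    panel.attrs["temp_coefs"] = dict(TEMP_COEFS)
    return panel


# ---------------------------------------------------------------------------
# Valley-bottom inputs and synthetic DEM tiles
# ---------------------------------------------------------------------------

def generate_valley_inputs(net: ReachNetwork, seed: int = 0) -> pd.DataFrame:
    """Per-reach confinement inputs from a mixture guaranteeing all classes.

    Mixture components target unconfined (high coverage, wide valleys), both
    moderately-confined clauses (narrow coverage with wide valleys; high
    coverage with intermediate width ratios), and confined geometry.  River
    width follows a hydraulic-geometry power law on discharge.
    """
    rng = substream(seed, "valley-inputs")
    n = len(net)
    q = net.reaches["mean_annual_q"].to_numpy(float)
    river_width = 7.2 * np.maximum(q, 1e-4) ** 0.5 \
        * np.exp(rng.normal(0, 0.1, n))
    comp = rng.choice(4, size=n, p=[0.45, 0.15, 0.15, 0.25])
    cov = np.empty(n)
    ratio = np.empty(n)
    draw = rng.normal(size=(n, 2))
    cov = np.select(
        [comp == 0, comp == 1, comp == 2, comp == 3],
        [np.clip(0.85 + 0.08 * draw[:, 0], 0.5, 1.0),
         np.clip(0.35 + 0.05 * draw[:, 0], 0.26, 0.49),
         np.clip(0.70 + 0.08 * draw[:, 0], 0.5, 1.0),
         np.clip(0.15 + 0.08 * draw[:, 0], 0.0, 0.24)])
    ratio = np.select(
        [comp == 0, comp == 1, comp == 2, comp == 3],
        [np.clip(7.0 + 1.2 * draw[:, 1], 4.0, None),
         np.clip(6.0 + 1.0 * draw[:, 1], 4.0, None),
         np.clip(3.0 + 0.4 * draw[:, 1], 2.0, 3.95),
         np.clip(1.2 + 0.4 * draw[:, 1], 0.0, 1.95)])
    inun_kind = rng.choice(3, size=n, p=[0.90, 0.03, 0.07])
    inundated = np.where(inun_kind == 1, 1.0,
                         np.where(inun_kind == 2, rng.uniform(0, 0.4, n), 0.0))
    out = pd.DataFrame({
        "comid": net.reaches["comid"].to_numpy(),
        "reach_length_km": net.reaches["length_km"].to_numpy(float),
        "river_width_m": river_width,
        "vb_width_m": ratio * river_width,
        "vb_length_coverage": cov,
        "inundated_fraction": inundated,
        "true_component": comp,
    })
    out.attrs["width_law"] = (7.2, 0.5)
    return out


def make_flat_dem(n_rows: int = 21, n_cols: int = 40, cell_size: float = 10.0,
                  elevation: float = 100.0):
    """Flat plane with the stream along the middle row."""
    dem = np.full((n_rows, n_cols), elevation)
    stream = [(n_rows // 2, c) for c in range(n_cols)]
    return dem, stream, cell_size


def make_v_valley_dem(side_slope: float, n_rows: int = 81, n_cols: int = 40,
                      cell_size: float = 10.0, channel_elev: float = 100.0):
    """Symmetric V-shaped valley: elevation rises ``side_slope`` per metre of
    lateral distance from the channel row.  Analytic valley half-width at
    flood height h is h / side_slope."""
    mid = n_rows // 2
    rows = np.abs(np.arange(n_rows) - mid) * cell_size * side_slope
    dem = channel_elev + np.tile(rows[:, None], (1, n_cols))
    stream = [(mid, c) for c in range(n_cols)]
    return dem, stream, cell_size


def make_canyon_dem(wall_height: float, n_rows: int = 21, n_cols: int = 40,
                    cell_size: float = 10.0, channel_elev: float = 100.0):
    """Vertical-walled canyon: only the channel row sits at channel level."""
    mid = n_rows // 2
    dem = np.full((n_rows, n_cols), channel_elev + wall_height)
    dem[mid, :] = channel_elev
    stream = [(mid, c) for c in range(n_cols)]
    return dem, stream, cell_size
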