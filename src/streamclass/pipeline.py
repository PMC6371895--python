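"""End-to-end orchestration of the six-layer classification.

One YAML/dict config drives the whole run: a generator block (or input CSV
paths), per-layer parameter blocks, layer toggles, and a single global seed.
Each layer draws from a named substream of that seed, so toggling one layer
never changes another layer's output, and a rerun with the same config is
byte-identical.  Outputs are one CSV per layer keyed by COMID plus a JSON
manifest recording the seed, a config hash, and per-layer unclassified
counts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bifurcation import assign_bifurcation_classes, correct_split_reaches
from .breaks import (
    DEFAULT_TEMPERATURE_BREAKS,
    TEMPERATURE_LABELS,
    assign_interval_classes,
    jenks_breaks,
    select_parsimonious_k,
)
from .confinement import confinement_table
from .errors import ConfigError, IntegrityError, StreamClassError
from .network import read_network
from .regimes import (
    cluster_ward,
    fit_class_extrapolator,
    fit_temperature_regressor,
    impute_missing,
    predict_class_membership,
    screen_reference_sites,
    summarize_assignment_probabilities,
)
from .seeds import subseed
from .size_gradient import UNCLASSIFIED, size_gradient_table
from .synth import (
    GeneratorConfig,
    attach_physical_attributes,
    generate_dendritic_network,
    generate_gage_panel,
    generate_temperature_sites,
    generate_valley_inputs,
)

ALL_LAYERS = ("size_gradient", "bifurcation", "hydrology", "temperature",
              "confinement")


class PipelineError(StreamClassError):
    """A layer failed; partial outputs are retained."""


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    """Hash of the run-defining configuration (output location excluded)."""
    payload = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def _build_network(config: dict, seed: int):
    if "inputs" in config:
        inp = config["inputs"]
        return read_network(inp["reach_table"], inp["fromto"],
                            inp.get("discharge_units", "m3s"))
    gen_kwargs = dict(config.get("generator", {}))
    gen_kwargs.setdefault("seed", subseed(seed, "generator"))
    gcfg = GeneratorConfig(**gen_kwargs)
    net = generate_dendritic_network(gcfg)
    return attach_physical_attributes(net, gcfg)


def run_pipeline(config: dict, outdir=None) -> dict:
    """Run the enabled layers and write per-layer CSVs plus a manifest.

    Returns the manifest dict.  On a layer failure the manifest (with the
    error recorded) and any completed layers are still written before a
    :class:`PipelineError` is raised.
    """
    if "seed" not in config:
        raise ConfigError("config must declare a seed")
    seed = int(config["seed"])
    outdir = Path(outdir or config.get("outdir", "streamclass_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    toggles = {layer: config.get("layers", {}).get(layer, True)
               for layer in ALL_LAYERS}
    manifest: dict = {
        "seed": seed,
        "config_hash": config_hash(config),
        "version": __version__,
        "layers": {},
        "unclassified_counts": {},
    }
    net = _build_network(config, seed)
    frames: dict[str, pd.DataFrame] = {}
    failed = None
    for layer in ALL_LAYERS:
        if not toggles[layer]:
            manifest["layers"][layer] = "skipped"
            continue
        try:
            frame, extra = _run_layer(layer, net, config, seed)
            frames[layer] = frame
            manifest["layers"][layer] = "ok"
            manifest["unclassified_counts"][layer] = _count_unclassified(frame)
            if extra:
                manifest.setdefault("diagnostics", {})[layer] = extra
        except Exception as exc:  # record, keep partial outputs, re-raise
            manifest["layers"][layer] = f"failed: {exc}"
            failed = (layer, exc)
            break
    write_outputs(frames, outdir, region_by_comid=_regions(net, config))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if failed:
        layer, exc = failed
        raise PipelineError(f"layer {layer!r} failed: {exc}") from exc
    return manifest


def _regions(net, config):
    col = config.get("region_column")
    if col is None:
        return None
    return dict(zip(net.reaches["comid"], net.reaches[col]))


def _count_unclassified(frame: pd.DataFrame) -> int:
    mask = pd.Series(False, index=frame.index)
    for col in frame.columns:
        if frame[col].dtype == object:
            mask |= frame[col] == UNCLASSIFIED
    return int(mask.sum())


def _run_layer(layer, net, config, seed):
    if layer == "size_gradient":
        return size_gradient_table(net), None
    if layer == "bifurcation":
        classes = assign_bifurcation_classes(net)
        return correct_split_reaches(net, classes), None
    if layer == "hydrology":
        return _hydrology_layer(net, config.get("hydrology", {}),
                                subseed(seed, "hydrology"))
    if layer == "temperature":
        return _temperature_layer(net, config.get("temperature", {}),
                                  subseed(seed, "temperature"))
    if layer == "confinement":
        inputs = generate_valley_inputs(net, seed=subseed(seed, "confinement"))
        out = confinement_table(inputs)
        cols = ["comid", "conf_class", "reach_length_km", "river_width_m",
                "vb_width_m", "vbl_rl_ratio", "vba_rwa_ratio",
                "inundated_fraction"]
        return out[cols], None
    raise ConfigError(f"unknown layer {layer!r}")


def _hydrology_layer(net, params, seed):
    panel = generate_gage_panel(
        net,
        n_sites=params.get("n_sites", 200),
        k_clusters=params.get("k_clusters", 4),
        separation=params.get("separation", 6.0),
        missing_frac=params.get("missing_frac", 0.02),
        seed=seed,
    )
    score_cols = panel.attrs["score_columns"]
    panel = impute_missing(panel, columns=score_cols, seed=seed)
    k_list = params.get("k_list", [2, 4])
    solutions = cluster_ward(panel[score_cols].to_numpy(), k_list)
    feature_cols = [c for c in net.reaches.columns
                    if c.startswith("hydro_cov_")] + ["elev_ws", "precip_ws",
                                                      "bfi_ws"]
    site_features = panel[["comid"]].merge(
        net.reaches[["comid"] + feature_cols], on="comid")[feature_cols]
    out = pd.DataFrame({"comid": net.reaches["comid"]})
    diags = []
    n_trees = params.get("n_trees", 500)
    for sol in solutions:
        model = fit_class_extrapolator(site_features, sol.labels, seed=seed,
                                       n_trees=n_trees)
        assign = predict_class_membership(
            model, net.reaches[feature_cols], comids=net.reaches["comid"])
        out[f"W{sol.k}"] = assign["label"].to_numpy()
        out[f"W{sol.k}_prob"] = assign["prob_max"].to_numpy()
        diags.append({"solution": f"W{sol.k}", "k": sol.k,
                      "n_obs": len(panel), "oob_error": model.oob_error,
                      "assignment": assign})
    summary = summarize_assignment_probabilities(diags)
    return out, summary.round(6).to_dict(orient="records")


def _temperature_layer(net, params, seed):
    sites = generate_temperature_sites(
        net,
        n_sites=params.get("n_sites", 400),
        noise_sd=params.get("noise_sd", 1.0),
        seed=seed,
    )
    reference = screen_reference_sites(sites)
    features = ["elev_ws", "lat", "mean_annual_q"]
    model = fit_temperature_regressor(
        reference, features, seed=seed, n_trees=params.get("n_trees", 500))
    pred = model.predict(net.reaches[features])
    mode = params.get("threshold_mode", "default")
    if mode == "default":
        classes = assign_interval_classes(pred, DEFAULT_TEMPERATURE_BREAKS,
                                          TEMPERATURE_LABELS)
    elif mode == "jenks":
        k = params.get("jenks_k") or select_parsimonious_k(
            pred, range(2, params.get("jenks_k_max", 9) + 1))
        res = jenks_breaks(pred, k)
        labels = [f"T{i + 1}" for i in range(k)]
        classes = assign_interval_classes(pred, res.breaks, labels)
    else:
        raise ConfigError(f"unknown threshold_mode {mode!r}")
    out = pd.DataFrame({
        "comid": net.reaches["comid"],
        "pred_july_august_temp": pred,
        "temp_class": classes,
    })
    extra = {"n_sites": len(sites), "n_reference": len(reference),
             "oob_r2": round(model.oob_r2, 6), "oob_mse": round(model.oob_mse, 6)}
    return out, extra


def write_outputs(frames: dict[str, pd.DataFrame], outdir,
                  region_by_comid: dict | None = None) -> list[Path]:
    """Write one CSV per layer (optionally split by region).

    Every frame must be keyed by a unique ``comid``; unclassified reaches
    are present with their explicit label, never dropped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for layer, frame in frames.items():
        if frame["comid"].duplicated().any():
            raise IntegrityError(f"duplicate COMID in layer {layer!r}")
        if region_by_comid is None:
            path = outdir / f"{layer}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
        else:
            regions = frame["comid"].map(region_by_comid)
            for region in sorted(regions.dropna().unique()):
                path = outdir / f"{layer}_{region}.csv"
                frame.loc[regions == region].to_csv(path, index=False)
                written.append(path)
    return written
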