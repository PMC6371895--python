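#!/usr/bin/env python
"""Temperature layer: reference screening, regression forest, Jenks breaks.

Screens synthetic monitoring sites to reference condition, fits the summer
temperature forest (Qwsa excluded), extrapolates July-August temperature to
every reach, and contrasts the data-driven Jenks partition with the shipped
fixed thresholds.
"""

from pathlib import Path

import pandas as pd

from streamclass.breaks import (
    DEFAULT_TEMPERATURE_BREAKS,
    TEMPERATURE_LABELS,
    assign_interval_classes,
    diagnostics_table,
    jenks_breaks,
    select_parsimonious_k,
)
from streamclass.network import read_network
from streamclass.regimes import fit_temperature_regressor, screen_reference_sites
from streamclass.synth import generate_temperature_sites

SEED = 1234
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    net = read_network(OUT / "reaches.csv", OUT / "fromto.csv")
    sites = generate_temperature_sites(net, n_sites=400, noise_sd=1.0,
                                       seed=SEED)
    reference = screen_reference_sites(sites)
    log = reference.attrs["screen_log"]
    print(f"screening kept {len(reference)}/{len(sites)} sites; rejections:",
          log["reason"].value_counts().to_dict())

    features = ["elev_ws", "lat", "mean_annual_q"]
    model = fit_temperature_regressor(reference, features, seed=SEED)
    print(f"temperature forest: OOB R^2 = {model.oob_r2:.3f}, "
          f"OOB MSE = {model.oob_mse:.3f} (deg C)^2")

    pred = model.predict(net.reaches[features])
    diag = diagnostics_table(pred, range(2, 11))
    diag.to_csv(OUT / "temperature_jenks_diagnostics.csv", index=False)
    k = select_parsimonious_k(pred, range(2, 11))
    res = jenks_breaks(pred, k)
    print(f"Jenks diagnostics plateau at k = {k}; breaks:",
          [round(b, 2) for b in res.breaks])
    print("fixed default thresholds:", list(DEFAULT_TEMPERATURE_BREAKS))

    out = pd.DataFrame({
        "comid": net.reaches["comid"],
        "pred_july_august_temp": pred,
        "temp_class": assign_interval_classes(
            pred, DEFAULT_TEMPERATURE_BREAKS, TEMPERATURE_LABELS),
    })
    out.to_csv(OUT / "temperature.csv", index=False)
    print("temperature class shares:",
          out["temp_class"].value_counts(normalize=True).round(3).to_dict())


if __name__ == "__main__":
    main()
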