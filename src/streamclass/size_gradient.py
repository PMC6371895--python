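"""Discharge-based size classes and slope-based gradient classes.

Size thresholds are derived as mid-points between median discharges of
consecutive Strahler orders; the shipped defaults are the published national
thresholds (m^3/s).  Gradient thresholds follow the Rosgen channel-morphology
breaks.  All binning is lower-inclusive / upper-exclusive with the last bin
open above; reaches with missing values receive an explicit "unclassified"
label rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DerivationError
from .network import ReachNetwork

UNCLASSIFIED = "unclassified"

SIZE_LABELS = ("HW", "SC", "LC", "SR", "MR", "MS", "LR", "GR")
#: National default size thresholds, m^3/s (HW < 0.057 <= SC < 0.283 <= ...).
DEFAULT_SIZE_BREAKS = (0.057, 0.283, 1.133, 5.663, 22.65, 70.79, 283.2)

GRADIENT_LABELS = ("VL", "L", "M", "MH", "H", "S")
#: Rosgen-style slope thresholds (rise/run).
DEFAULT_GRADIENT_BREAKS = (0.001, 0.005, 0.02, 0.04, 0.1)


@dataclass
class SizeThresholds:
    """Ordered discharge breakpoints with derivation diagnostics."""

    breaks: tuple[float, ...]
    labels: tuple[str, ...]
    medians: dict[int, float] | None = None  # order -> median discharge

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breaks) + 1:
            raise ValueError("need exactly one more label than breaks")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")


DEFAULT_SIZE_THRESHOLDS = SizeThresholds(DEFAULT_SIZE_BREAKS, SIZE_LABELS)


def bin_values(values, breaks, labels) -> list[str]:
    """Lower-inclusive/upper-exclusive binning; NaN -> unclassified."""
    breaks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    if len(labels) != len(breaks) + 1:
        raise ValueError("need exactly one more label than breaks")
    out = []
    for v in np.asarray(values, dtype=float):
        if np.isnan(v):
            out.append(UNCLASSIFIED)
        else:
            out.append(labels[int(np.searchsorted(breaks, v, side="right"))])
    return out


def derive_size_thresholds(net: ReachNetwork) -> SizeThresholds:
    """Mid-points between per-order median discharges as size thresholds.

    Requires at least two Strahler orders and medians that increase with
    order; a non-monotone median sequence indicates the discharge attribute
    does not scale with the network and is reported as an error.
    """
    r = net.reaches
    med = r.groupby("strahler_order")["mean_annual_q"].median()
    orders = sorted(med.index)
    if len(orders) < 2:
        raise DerivationError("need at least two Strahler orders to derive breaks")
    offending = [
        (o1, o2) for o1, o2 in zip(orders, orders[1:]) if med[o2] <= med[o1]
    ]
    if offending:
        raise DerivationError(f"non-monotone order medians at {offending}")
    breaks = tuple(
        (med[o1] + med[o2]) / 2.0 for o1, o2 in zip(orders, orders[1:])
    )
    labels = SIZE_LABELS[: len(breaks) + 1]
    return SizeThresholds(breaks, labels, medians={int(o): float(med[o]) for o in orders})


def assign_size_classes(
    net: ReachNetwork, thresholds: SizeThresholds = DEFAULT_SIZE_THRESHOLDS
) -> pd.DataFrame:
    """One size class per reach from its mean annual discharge (m^3/s)."""
    q = net.reaches["mean_annual_q"].to_numpy(float)
    if (q[~np.isnan(q)] < 0).any():
        raise ValueError("negative discharge")
    return pd.DataFrame({
        "comid": net.reaches["comid"],
        "size_class": bin_values(q, thresholds.breaks, thresholds.labels),
    })


def assign_gradient_classes(
    net: ReachNetwork,
    breaks=DEFAULT_GRADIENT_BREAKS,
    labels=GRADIENT_LABELS,
) -> pd.DataFrame:
    """One gradient class per reach from its slope (rise/run)."""
    s = net.reaches["slope"].to_numpy(float)
    if (s[~np.isnan(s)] < 0).any():
        raise ValueError("negative slope")
    return pd.DataFrame({
        "comid": net.reaches["comid"],
        "gradient_class": bin_values(s, breaks, labels),
    })


def size_gradient_table(
    net: ReachNetwork, thresholds: SizeThresholds = DEFAULT_SIZE_THRESHOLDS
) -> pd.DataFrame:
    """Joined per-reach export: COMID, classes, order, Q (m^3/s), slope."""
    size = assign_size_classes(net, thresholds)
    grad = assign_gradient_classes(net)
    out = size.merge(grad, on="comid")
    out["StreamOrde"] = net.reaches["strahler_order"].to_numpy()
    out["mean_annual_q"] = net.reaches["mean_annual_q"].to_numpy(float)
    out["slope"] = net.reaches["slope"].to_numpy(float)
    return out
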