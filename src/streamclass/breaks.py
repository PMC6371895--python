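"""Fisher-Jenks optimal univariate partitioning and fixed-interval binning.

The Jenks "natural breaks" classifier finds the contiguous partition of the
sorted values that minimizes total within-class sum of squared deviations,
via the exact Fisher dynamic program (no heuristics).  Diagnostics follow
map-classification practice: goodness of variance fit (GVF) on squared
deviations and its absolute-deviation analog, here called tabular accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np

from .size_gradient import UNCLASSIFIED, bin_values

#: Default temperature classes (deg C): VC < 10 <= CD < 15 <= CC < 18 <= ...
TEMPERATURE_LABELS = ("VC", "CD", "CC", "CL", "CW", "W")
DEFAULT_TEMPERATURE_BREAKS = (10.0, 15.0, 18.0, 21.0, 24.0)


@dataclass
class JenksResult:
    """Optimal k-class contiguous partition of a univariate sample."""

    k: int
    breaks: tuple[float, ...]       # max value of each class but the last
    class_of: np.ndarray            # class index (0-based) per input value
    ssd: float                      # within-class sum of squared deviations
    gvf: float
    tabular_accuracy: float


def jenks_breaks(values, k: int) -> JenksResult:
    """Exact Fisher-Jenks partition of ``values`` into ``k`` classes.

    Dynamic program over the sorted sample: cost(j, m) = minimal SSE of the
    first j values in m classes.  O(k n^2) time, O(k n) memory; deterministic,
    ties resolved toward the smallest class-boundary index.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    if k < 2 or k > n:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    prefix = np.concatenate([[0.0], np.cumsum(v)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(v * v)])
    # cost[m][j]: best SSE of v[:j] in m classes; cut[m][j]: start of last class
    cost = np.full((k + 1, n + 1), np.inf)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            i = np.arange(m - 1, j)  # start of the last class, vectorized
            seg = (prefix_sq[j] - prefix_sq[i]) \
                - (prefix[j] - prefix[i]) ** 2 / (j - i)
            total = cost[m - 1, i] + seg
            best_i = int(np.argmin(total))  # first minimum: smallest boundary
            cost[m, j] = total[best_i]
            cut[m, j] = i[best_i]
    # Backtrack boundaries.
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = cut[m, j]
        bounds.append(j)
    bounds = bounds[::-1]  # [0, ..., n]
    class_of_sorted = np.empty(n, dtype=int)
    for ci, (i, j) in enumerate(zip(bounds, bounds[1:])):
        class_of_sorted[i:j] = ci
    order = np.argsort(np.asarray(values, dtype=float), kind="stable")
    class_of = np.empty(n, dtype=int)
    class_of[order] = class_of_sorted
    breaks = tuple(float(v[j - 1]) for j in bounds[1:-1])
    ssd = float(cost[k, n])
    gvf, ta = break_diagnostics_from_classes(np.asarray(values, float), class_of)
    return JenksResult(k, breaks, class_of, ssd, gvf, ta)


def break_diagnostics_from_classes(values: np.ndarray, class_of: np.ndarray):
    """(GVF, tabular accuracy) of a given class assignment.

    GVF = 1 - SDCM/SDAM with squared deviations about class means vs the
    grand mean; tabular accuracy substitutes absolute deviations.  Constant
    data (zero total deviation) is defined as perfectly fit.
    """
    values = np.asarray(values, dtype=float)
    grand = values.mean()
    sdam = float(np.sum((values - grand) ** 2))
    adam = float(np.sum(np.abs(values - grand)))
    sdcm = adcm = 0.0
    for c in np.unique(class_of):
        sub = values[class_of == c]
        sdcm += float(np.sum((sub - sub.mean()) ** 2))
        adcm += float(np.sum(np.abs(sub - sub.mean())))
    gvf = 1.0 if sdam == 0 else 1.0 - sdcm / sdam
    ta = 1.0 if adam == 0 else 1.0 - adcm / adam
    return gvf, ta


def break_diagnostics(values, breaks):
    """(GVF, tabular accuracy) for explicit right-closed class maxima."""
    values = np.asarray(values, dtype=float)
    class_of = np.searchsorted(np.asarray(breaks, float), values, side="left")
    return break_diagnostics_from_classes(values, class_of)


def diagnostics_table(values, k_range=range(2, 21)):
    """Jenks diagnostics (k, gvf, tabular_accuracy) over a range of k."""
    import pandas as pd

    rows = []
    for k in k_range:
        res = jenks_breaks(values, k)
        rows.append({"k": k, "gvf": res.gvf, "tabular_accuracy": res.tabular_accuracy})
    return pd.DataFrame(rows)


def plateau_k(ks, gvf_seq, ta_seq, plateau_delta: float = 0.02) -> int:
    """Smallest k whose successor improves neither diagnostic by
    ``plateau_delta``; falls back to the largest k (with a warning)."""
    for idx, k in enumerate(ks[:-1]):
        dg = gvf_seq[idx + 1] - gvf_seq[idx]
        dt = ta_seq[idx + 1] - ta_seq[idx]
        if dg < plateau_delta and dt < plateau_delta:
            return k
    warn("no diagnostic plateau within k_range; returning its maximum")
    return ks[-1]


def select_parsimonious_k(values, k_range=range(2, 21),
                          plateau_delta: float = 0.02) -> int:
    """Smallest k past which both Jenks diagnostics plateau on ``values``."""
    ks = sorted(k_range)
    diag = [jenks_breaks(values, k) for k in ks + [ks[-1] + 1]]
    return plateau_k(ks + [ks[-1] + 1],
                     [d.gvf for d in diag],
                     [d.tabular_accuracy for d in diag],
                     plateau_delta)


def assign_interval_classes(values, thresholds=DEFAULT_TEMPERATURE_BREAKS,
                            labels=TEMPERATURE_LABELS) -> list[str]:
    """Fixed-interval (lower-inclusive, upper-exclusive) class labels."""
    return bin_values(values, thresholds, labels)
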