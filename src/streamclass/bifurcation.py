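"""Tributary-junction (bifurcation) coding and divergence classification.

Each reach is coded by the combination of Strahler orders meeting at its
upstream end: an order-1 and an order-2 tributary feeding an order-2 reach
yields "2.12"; a headwater with no upstream confluence is "1_0".  Up to four
upstream orders are retained.  Channel divergences are classified as main
(D1) or secondary (D2) channels, rejoins of divergent channels as DU, and
junctions whose order arithmetic is inconsistent with an unflagged Strahler
combination as a generic divergence class D.  Reaches split at unmeaningful
points (quadrangle map boundaries) are corrected through their ecological
unit: every member inherits the class of the upstream-most reach.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .network import (
    ReachNetwork,
    count_downstream,
    count_upstream,
    strahler_combine,
    upstream_of,
)

DIVERGENCE_CLASSES = ("D1", "D2", "DU", "D", "none")

MAX_UPSTREAM_ORDERS = 4


@dataclass(frozen=True)
class JunctionCode:
    """Rendered tributary-mainstem combination for one reach."""

    downstream_order: int
    upstream_orders: tuple[int, ...]
    rendered: str


def code_junction(
    downstream_order: int, upstream_orders, sort_mode: str = "auto"
) -> JunctionCode:
    """Render the junction class for a reach.

    No upstream confluence (zero or one upstream reach) renders as
    "<order>_0".  With exactly two tributaries the digits sort ascending
    ("2.12"); with three or four, the order matching the downstream reach
    leads and the remainder sorts descending ("5.511").  More than four
    contributors keep the largest four.  Orders of 10 or more cannot be
    single digits and render as hyphen-joined tokens ("12.10-3").

    ``sort_mode`` may force "ascending" or "descending" for all arities.
    """
    if downstream_order < 1:
        raise ValueError("downstream order must be >= 1")
    ups = sorted(int(o) for o in upstream_orders)
    if any(o < 1 for o in ups):
        raise ValueError("upstream orders must be >= 1")
    if len(ups) > MAX_UPSTREAM_ORDERS:
        ups = ups[-MAX_UPSTREAM_ORDERS:]  # keep the largest four
    if len(ups) <= 1:
        return JunctionCode(downstream_order, tuple(ups), f"{downstream_order}_0")
    if sort_mode == "ascending" or (sort_mode == "auto" and len(ups) == 2):
        ordered = sorted(ups)
    elif sort_mode == "descending":
        ordered = sorted(ups, reverse=True)
    elif sort_mode == "auto":
        ordered = sorted(ups, reverse=True)
        if downstream_order in ordered:
            ordered.remove(downstream_order)
            ordered = [downstream_order] + ordered
    else:
        raise ValueError(f"unknown sort_mode {sort_mode!r}")
    if downstream_order >= 10 or any(o >= 10 for o in ordered):
        rendered = f"{downstream_order}." + "-".join(str(o) for o in ordered)
    else:
        rendered = f"{downstream_order}." + "".join(str(o) for o in ordered)
    return JunctionCode(downstream_order, tuple(ordered), rendered)


def detect_nonsensical_junctions(net: ReachNetwork) -> set[int]:
    """Reaches below junctions inconsistent with Strahler order arithmetic.

    A junction is flagged when >= 2 reaches merge upstream, neither they nor
    the downstream reach carry a divergence designation, and the downstream
    order differs from the Strahler combination of the upstream orders —
    the signature of a divergence the source hydrography failed to code.
    """
    order = dict(zip(net.reaches["comid"], net.reaches["strahler_order"]))
    flags = dict(zip(net.reaches["comid"], net.reaches["divergence_flag"]))
    out: set[int] = set()
    for comid in net.comids:
        ups = upstream_of(net, comid)
        if len(ups) < 2 or flags[comid] != "none":
            continue
        if any(flags[u] != "none" for u in ups):
            continue
        if order[comid] != strahler_combine([order[u] for u in ups]):
            out.add(comid)
    return out


def assign_divergence_classes(net: ReachNetwork) -> dict[int, str]:
    """D1/D2 from divergence flags, DU below rejoining divergent channels,
    D for detected non-sensical junctions, none otherwise."""
    flags = dict(zip(net.reaches["comid"], net.reaches["divergence_flag"]))
    nonsense = detect_nonsensical_junctions(net)
    # Trace flagged divergence channels downstream: branch_of[r] holds
    # (divergence parent, channel head) pairs r lies on.
    branch_of: dict[int, set[tuple[int, int]]] = {c: set() for c in net.comids}
    du: set[int] = set()
    for comid in net.toposort():
        ups = upstream_of(net, comid)
        if flags[comid] in ("main", "secondary"):
            for parent in ups:
                branch_of[comid].add((parent, comid))
            continue
        inherited: set[tuple[int, int]] = set()
        for u in ups:
            inherited |= branch_of[u]
        by_parent: dict[int, set[int]] = {}
        for parent, head in inherited:
            by_parent.setdefault(parent, set()).add(head)
        if any(len(heads) >= 2 for heads in by_parent.values()):
            du.add(comid)  # channels of one divergence re-merge here
        elif len(ups) == 1:
            branch_of[comid] = inherited  # still on a single channel
    out: dict[int, str] = {}
    for comid in net.comids:
        if flags[comid] == "main":
            out[comid] = "D1"
        elif flags[comid] == "secondary":
            out[comid] = "D2"
        elif comid in du:
            out[comid] = "DU"
        elif comid in nonsense:
            out[comid] = "D"
        else:
            out[comid] = "none"
    return out


def assign_bifurcation_classes(
    net: ReachNetwork, sort_mode: str = "auto"
) -> pd.DataFrame:
    """Per-reach bifurcation table: junction code, divergence class, counts.

    Every reach receives exactly one non-empty bifurcation class; reaches in
    the generic divergence class D carry "D" as their bifurcation class as
    well, since their junction arithmetic is untrustworthy.
    """
    order = dict(zip(net.reaches["comid"], net.reaches["strahler_order"]))
    eco = dict(zip(net.reaches["comid"], net.reaches["eco_unit_id"]))
    div = assign_divergence_classes(net)
    nonsense = detect_nonsensical_junctions(net)
    ups_count = count_upstream(net)
    down_count = count_downstream(net)
    rows = []
    for comid in net.comids:
        ups = upstream_of(net, comid)
        if div[comid] == "D":
            bif = "D"
        else:
            bif = code_junction(order[comid], [order[u] for u in ups],
                                sort_mode).rendered
        rows.append({
            "comid": comid,
            "bif_class": bif,
            "div_class": div[comid],
            "upstream_count": ups_count[comid],
            "downstream_count": down_count[comid],
            "eco_unit_id": eco[comid],
            "flagged": comid in nonsense,
        })
    return pd.DataFrame(rows)


def correct_split_reaches(net: ReachNetwork, classes: pd.DataFrame) -> pd.DataFrame:
    """Propagate the upstream-most member's classes through each eco unit.

    ``classes`` must carry comid, bif_class, div_class and eco_unit_id
    columns (as produced by :func:`assign_bifurcation_classes`).  Units whose
    members do not form a connected directed path are skipped with a warning.
    Idempotent: the upstream-most member's class is a fixed point.
    """
    out = classes.copy()
    units = out.loc[out["eco_unit_id"].notna()].groupby("eco_unit_id")
    idx_of = {c: i for i, c in enumerate(out["comid"])}
    for unit, members in units:
        comids = set(members["comid"].astype(int))
        if len(comids) == 1:
            continue
        head = _path_head(net, comids)
        if head is None:
            warnings.warn(f"eco unit {unit} is not a connected directed path; skipped")
            continue
        for c in comids:
            out.iloc[idx_of[c], out.columns.get_loc("bif_class")] = \
                out.iloc[idx_of[head]]["bif_class"]
            out.iloc[idx_of[c], out.columns.get_loc("div_class")] = \
                out.iloc[idx_of[head]]["div_class"]
    return out


def _path_head(net: ReachNetwork, comids: set[int]):
    """Upstream-most member if the set forms a directed chain, else None."""
    heads = [c for c in comids
             if not any(u in comids for u in upstream_of(net, c))]
    if len(heads) != 1:
        return None
    # walk downstream within the unit, confirming a simple chain
    seen = {heads[0]}
    cur = heads[0]
    while True:
        nxt = [d for d in net.downstream_of(cur) if d in comids]
        if not nxt:
            break
        if len(nxt) > 1:
            return None
        cur = nxt[0]
        if cur in seen:
            return None
        seen.add(cur)
    return heads[0] if seen == comids else None
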