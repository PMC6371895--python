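"""Reach-network data model, CSV readers/writers, and graph utilities.

The network is purely tabular: a reach attribute table keyed by COMID and a
"from-to" edge table (upstream COMID -> downstream COMID), mirroring the
NHDPlus V2 flowline export dialect.  Geometry is deliberately out of the data
model; every layer of the classification needs only topology and attributes.

Discharge is held internally in m^3/s.  NHDPlus ships mean annual flow in
cfs; the reader converts at ingest when the unit tag says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError, SchemaError, TopologyError

CFS_TO_CMS = 0.0283168

#: Column names of the external CSV dialect -> internal names.
_REACH_COLUMNS = {
    "COMID": "comid",
    "StreamOrde": "strahler_order",
    "LENGTHKM": "length_km",
    "slope": "slope",
    "Q0001A": "mean_annual_q",
    "Divergence": "divergence_flag",
    "EcoUnitID": "eco_unit_id",
    "InundatedFrac": "inundated_fraction",
}
_FROMTO_COLUMNS = ("FROMCOMID", "TOCOMID")

#: NHDPlus divergence coding: 0 = not part of a divergence, 1 = main (D1)
#: channel, 2 = secondary (D2) channel.
_DIV_CODE_TO_FLAG = {0: "none", 1: "main", 2: "secondary"}
_DIV_FLAG_TO_CODE = {v: k for k, v in _DIV_CODE_TO_FLAG.items()}

DIVERGENCE_FLAGS = ("none", "main", "secondary")


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_topology`; empty report iff invariants hold."""

    cycles: list[list[int]] = field(default_factory=list)
    orphans: list[int] = field(default_factory=list)
    missing_divergence_flags: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.cycles or self.orphans or self.missing_divergence_flags)


class ReachNetwork:
    """A directed reach graph with per-reach physical attributes.

    Parameters
    ----------
    reaches
        One row per reach.  Required columns: ``comid``, ``strahler_order``,
        ``length_km``, ``slope``, ``mean_annual_q`` (m^3/s),
        ``divergence_flag`` (none/main/secondary), ``eco_unit_id`` (nullable),
        ``inundated_fraction``.  Any further numeric columns are treated as
        predictor attributes.
    edges
        ``(from_comid, to_comid)`` pairs, upstream -> downstream.
    """

    def __init__(self, reaches: pd.DataFrame, edges: list[tuple[int, int]]):
        reaches = reaches.reset_index(drop=True)
        if "eco_unit_id" in reaches.columns:  # normalize NaN/None to None
            col = reaches["eco_unit_id"].astype(object)
            reaches["eco_unit_id"] = col.where(pd.notna(col), None)
        if reaches["comid"].duplicated().any():
            dupes = reaches.loc[reaches["comid"].duplicated(), "comid"].tolist()
            raise IntegrityError(f"duplicate COMID(s): {dupes}")
        known = set(reaches["comid"].astype(int))
        for u, v in edges:
            if u == v:
                raise IntegrityError(f"self-loop on COMID {u}")
            if u not in known or v not in known:
                missing = u if u not in known else v
                raise IntegrityError(f"from-to row references absent COMID {missing}")
        self.reaches = reaches
        self.edges = [(int(u), int(v)) for u, v in edges]
        self.meta: dict = {}  # generator ground truth, unit provenance, ...
        self._build_index()

    def _build_index(self) -> None:
        self._down: dict[int, list[int]] = {}
        self._up: dict[int, list[int]] = {}
        for c in self.reaches["comid"].astype(int):
            self._down[c] = []
            self._up[c] = []
        for u, v in self.edges:
            self._down[u].append(v)
            self._up[v].append(u)
        for d in (self._down, self._up):
            for c in d:
                d[c].sort()

    # -- basic accessors ---------------------------------------------------
    @property
    def comids(self) -> list[int]:
        return self.reaches["comid"].astype(int).tolist()

    def __len__(self) -> int:
        return len(self.reaches)

    def downstream_of(self, comid: int) -> list[int]:
        try:
            return list(self._down[comid])
        except KeyError:
            raise KeyError(f"unknown COMID {comid}") from None

    def attribute(self, comid: int, column: str):
        row = self.reaches.loc[self.reaches["comid"] == comid]
        if row.empty:
            raise KeyError(f"unknown COMID {comid}")
        return row.iloc[0][column]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.comids)
        g.add_edges_from(self.edges)
        return g

    def copy(self) -> "ReachNetwork":
        out = ReachNetwork(self.reaches.copy(), list(self.edges))
        out.meta = dict(self.meta)
        return out

    def toposort(self) -> list[int]:
        """Upstream-to-downstream order; raises on cycles."""
        try:
            return list(nx.lexicographical_topological_sort(self.graph()))
        except nx.NetworkXUnfeasible:
            raise TopologyError("network contains a cycle") from None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_network(
    reach_table_path, fromto_path, discharge_units: str = "m3s"
) -> ReachNetwork:
    """Read a reach attribute CSV and a from-to CSV into a validated network.

    ``discharge_units`` declares the unit of the ``Q0001A`` column: ``"m3s"``
    (stored as-is) or ``"cfs"`` (converted by x0.0283168).
    """
    if discharge_units not in ("m3s", "cfs"):
        raise ConfigError(f"unknown discharge unit tag {discharge_units!r}")
    raw = pd.read_csv(reach_table_path)
    for col in _REACH_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"reach table missing required column {col!r}")
    reaches = raw.rename(columns=_REACH_COLUMNS)
    reaches["comid"] = reaches["comid"].astype(int)
    reaches["divergence_flag"] = (
        reaches["divergence_flag"].astype(int).map(_DIV_CODE_TO_FLAG)
    )
    if reaches["divergence_flag"].isna().any():
        raise SchemaError("Divergence column must be coded 0/1/2")
    if discharge_units == "cfs":
        reaches["mean_annual_q"] = reaches["mean_annual_q"] * CFS_TO_CMS

    ft = pd.read_csv(fromto_path)
    for col in _FROMTO_COLUMNS:
        if col not in ft.columns:
            raise SchemaError(f"from-to table missing required column {col!r}")
    edges = list(zip(ft["FROMCOMID"].astype(int), ft["TOCOMID"].astype(int)))
    net = ReachNetwork(reaches, edges)
    net.meta["discharge_units_input"] = discharge_units
    return net


def write_network(net: ReachNetwork, reach_table_path, fromto_path) -> None:
    """Write the network back in the same CSV dialect (discharge in m^3/s)."""
    inv = {v: k for k, v in _REACH_COLUMNS.items()}
    out = net.reaches.rename(columns=inv).copy()
    out["Divergence"] = net.reaches["divergence_flag"].map(_DIV_FLAG_TO_CODE)
    cols = list(_REACH_COLUMNS) + [
        c for c in out.columns if c not in _REACH_COLUMNS
    ]
    out[cols].to_csv(reach_table_path, index=False)
    pd.DataFrame(net.edges, columns=list(_FROMTO_COLUMNS)).to_csv(
        fromto_path, index=False
    )


# ---------------------------------------------------------------------------
# Topology utilities
# ---------------------------------------------------------------------------

def validate_topology(net: ReachNetwork) -> ValidationReport:
    """Report cycles, orphans, and unflagged divergences (never raises)."""
    g = net.graph()
    report = ValidationReport()
    report.cycles = [sorted(c) for c in nx.simple_cycles(g)]
    if len(net) > 1:
        touched = {u for u, _ in net.edges} | {v for _, v in net.edges}
        report.orphans = sorted(set(net.comids) - touched)
    flags = dict(zip(net.reaches["comid"], net.reaches["divergence_flag"]))
    for comid in net.comids:
        children = net.downstream_of(comid)
        if len(children) > 1 and all(flags[c] == "none" for c in children):
            report.missing_divergence_flags.append(comid)
    return report


def upstream_of(net: ReachNetwork, comid: int) -> list[int]:
    """Immediate upstream COMIDs, ascending; empty for headwaters."""
    try:
        return list(net._up[comid])
    except KeyError:
        raise KeyError(f"unknown COMID {comid}") from None


def strahler_combine(upstream_orders: list[int]) -> int:
    """Strahler rule for a junction: max+1 if the max order is shared by >=2
    tributaries, else the max; 1 for a headwater."""
    if not upstream_orders:
        return 1
    m = max(upstream_orders)
    return m + 1 if sum(o == m for o in upstream_orders) >= 2 else m


def compute_strahler_order(net: ReachNetwork) -> dict[int, int]:
    """Strahler order per reach on a DAG.

    Headwaters are order 1.  At a junction the order increments only when two
    or more *independent* tributaries share the maximal order: channels
    flagged as secondary (D2) divergences are excluded from that count (a
    stream rejoining its own divergence is not a new tributary) but still
    bound the maximum, so secondary channels inherit the parent order.
    """
    order: dict[int, int] = {}
    flags = dict(zip(net.reaches["comid"], net.reaches["divergence_flag"]))
    for comid in net.toposort():
        ups = upstream_of(net, comid)
        if not ups:
            order[comid] = 1
            continue
        m = max(order[u] for u in ups)
        n_at_max = sum(
            1 for u in ups if order[u] == m and flags[u] != "secondary"
        )
        order[comid] = m + 1 if n_at_max >= 2 else m
    return order


def accumulate_upstream(
    net: ReachNetwork, field_name: str, secondary_fraction: float = 0.0
) -> dict[int, float]:
    """Accumulate a numeric reach attribute down the network.

    value(reach) = local value + routed sum of upstream accumulations.  At a
    divergence the parent's accumulation routes entirely down the main (D1)
    channel by default (``secondary_fraction=0``) to avoid double counting;
    each secondary child may instead receive ``secondary_fraction`` of it.
    """
    if field_name not in net.reaches.columns:
        raise SchemaError(f"no reach attribute {field_name!r}")
    local = dict(zip(net.reaches["comid"], net.reaches[field_name]))
    if any(pd.isna(v) for v in local.values()):
        raise SchemaError(f"attribute {field_name!r} missing on some reaches")
    flags = dict(zip(net.reaches["comid"], net.reaches["divergence_flag"]))
    acc: dict[int, float] = {}
    for comid in net.toposort():
        total = float(local[comid])
        for u in upstream_of(net, comid):
            total += _routing_weight(net, flags, u, comid, secondary_fraction) * acc[u]
        acc[comid] = total
    return acc


def _routing_weight(net, flags, parent, child, secondary_fraction) -> float:
    children = net.downstream_of(parent)
    if len(children) <= 1:
        return 1.0
    n_sec = sum(1 for c in children if flags[c] == "secondary")
    n_main = len(children) - n_sec
    if flags[child] == "secondary":
        return secondary_fraction
    # non-secondary children share whatever the secondaries do not take
    return (1.0 - secondary_fraction * n_sec) / max(n_main, 1)


def count_upstream(net: ReachNetwork) -> dict[int, int]:
    """Number of immediate upstream reaches per reach."""
    return {c: len(upstream_of(net, c)) for c in net.comids}


def count_downstream(net: ReachNetwork) -> dict[int, int]:
    """Number of immediate downstream reaches per reach."""
    return {c: len(net.downstream_of(c)) for c in net.comids}
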