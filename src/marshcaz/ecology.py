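"""Productivity index and the taxon <-> CAZyme bipartite network.

The productivity index asks whether a taxon secretes more CAZymes than
its standing stock predicts:

    PI = log10( sigma x-bar mol% / relative abundance )

with both terms on the percent scale, so PI = 0 means output exactly
proportional to abundance.  A taxon is flagged "disproportionately
productive" when PI > 0.3 (about twofold) at one or more time points.

The bipartite network connects taxonomic groups to the CAZyme families
they produce; node and edge weights are sigma x-bar mol% averaged across
the whole time course (absent time points counting as zero), and the
graph is then pruned of negligible nodes for presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .annotax import family_to_class
from .errors import ParameterError

PI_FLAG_THRESHOLD = 0.3


def productivity_index(sum_mean_mol_pct: float, abundance: float) -> float:
    """log10(sigma x-bar mol% / abundance); both arguments in percent."""
    if sum_mean_mol_pct <= 0 or abundance <= 0:
        raise ParameterError(
            "productivity index undefined for non-positive arguments: "
            f"mol%={sum_mean_mol_pct}, abundance={abundance}"
        )
    return math.log10(sum_mean_mol_pct / abundance)


def productivity_table(
    contributions: pd.DataFrame,
    abundances: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(taxon, week) PI records.

    ``contributions``: columns taxon, week, sum_mean_mol_pct.
    ``abundances``: columns taxon, week, abundance (percent, replicate
    mean).  Taxa secreting CAZymes but absent from the community profile
    (abundance 0 or no row) get index NA with a reason — these are the
    "not identified in the community profile" cases reported separately,
    never given an index.
    """
    merged = contributions.merge(abundances, on=["taxon", "week"], how="left")
    merged["abundance"] = merged["abundance"].fillna(0.0)
    rows = []
    for _, r in merged.iterrows():
        if r["sum_mean_mol_pct"] > 0 and r["abundance"] > 0:
            idx = productivity_index(r["sum_mean_mol_pct"], r["abundance"])
            reason = ""
        else:
            idx = np.nan
            reason = (
                "not in community profile" if r["abundance"] <= 0 else "no CAZyme output"
            )
        rows.append(
            {
                "taxon": r["taxon"],
                "week": r["week"],
                "sum_mean_mol_pct": r["sum_mean_mol_pct"],
                "abundance": r["abundance"],
                "index": idx,
                "na_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def flag_productive(records: pd.DataFrame, threshold: float = PI_FLAG_THRESHOLD) -> set[str]:
    """Taxa with PI strictly above ``threshold`` at >= 1 time point."""
    ok = records.dropna(subset=["index"])
    flagged = ok.loc[ok["index"] > threshold, "taxon"]
    return set(flagged)


def build_network(contributions: pd.DataFrame, weeks: list | None = None) -> nx.Graph:
    """Weighted bipartite taxon <-> CAZyme-family graph.

    ``contributions``: columns taxon, cazyme_family, week,
    sum_mean_mol_pct.  Node and edge weights are the mean over the time
    course (``weeks`` — default every week present in the input), with a
    missing (taxon, family, week) combination counting as zero.  Family
    nodes carry a ``cazy_class`` attribute for colouring.
    """
    g = nx.Graph()
    if contributions.empty:
        return g
    if weeks is None:
        weeks = sorted(contributions["week"].unique())
    n_weeks = len(weeks)
    if n_weeks == 0:
        raise ParameterError("no time points to average over")
    sub = contributions[contributions["week"].isin(weeks)]
    edge_w = (
        sub.groupby(["taxon", "cazyme_family"])["sum_mean_mol_pct"].sum() / n_weeks
    )
    for (taxon, family), w in edge_w.items():
        t_node = ("taxon", taxon)
        f_node = ("cazyme", family)
        if t_node not in g:
            g.add_node(t_node, bipartite="taxon", label=taxon, weight=0.0)
        if f_node not in g:
            g.add_node(
                f_node,
                bipartite="cazyme",
                label=family,
                cazy_class=family_to_class(family),
                weight=0.0,
            )
        g.add_edge(t_node, f_node, weight=float(w))
        g.nodes[t_node]["weight"] += float(w)
        g.nodes[f_node]["weight"] += float(w)
    return g


def filter_network(
    net: nx.Graph,
    taxon_min: float = 0.025,
    taxon_max_edges: int = 5,
    cazyme_min: float = 1.25e-3,
) -> nx.Graph:
    """Prune negligible nodes for presentation.

    CAZyme-family nodes with weight < ``cazyme_min`` are removed first;
    then taxon nodes are removed when BOTH weight < ``taxon_min`` AND
    degree <= ``taxon_max_edges`` (degree evaluated after the CAZyme
    removal).  Incident edges go with their nodes.  Idempotent.
    """
    g = net.copy()
    drop_caz = [
        n for n, d in g.nodes(data=True)
        if d.get("bipartite") == "cazyme" and d["weight"] < cazyme_min
    ]
    g.remove_nodes_from(drop_caz)
    drop_tax = [
        n for n, d in g.nodes(data=True)
        if d.get("bipartite") == "taxon"
        and d["weight"] < taxon_min
        and g.degree(n) <= taxon_max_edges
    ]
    g.remove_nodes_from(drop_tax)
    return g


def network_tables(net: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge TSV-ready frames for a built network."""
    nodes = pd.DataFrame(
        [
            {
                "node": d["label"],
                "kind": d["bipartite"],
                "cazy_class": d.get("cazy_class", ""),
                "weight": d["weight"],
            }
            for _, d in net.nodes(data=True)
        ]
    )
    edges = pd.DataFrame(
        [
            {
                "taxon": (u if u[0] == "taxon" else v)[1],
                "cazyme_family": (u if u[0] == "cazyme" else v)[1],
                "weight": d["weight"],
            }
            for u, v, d in net.edges(data=True)
        ]
    )
    return nodes, edges
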