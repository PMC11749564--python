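"""GO overrepresentation per cluster with redundancy collapse.

Per (cluster, GO term) a 2x2 table is tested with the two-sided Fisher
exact test (point-probability convention) against the background of all
annotated transcripts in the reference; odds ratios are reported and
Benjamini-Hochberg FDR is applied per cluster. Only GO categories
containing more than five DE transcripts of the cluster are considered.
Significant GO terms whose gene sets overlap strongly (overlap
coefficient |A∩B| / min(|A|,|B|) > 0.8) are collapsed into clusters of
redundant terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .de import bh_adjust


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for table [[a, b], [c, d]].

    The p-value sums hypergeometric outcomes (margins fixed) whose point
    probability does not exceed the observed table's. The odds ratio is
    (a*d)/(b*c), with Haldane's +0.5 added to every cell iff any cell is
    zero.
    """
    cells = (a, b, c, d)
    if any(v < 0 or v != int(v) for v in cells):
        raise ValueError("cells must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("all-zero 2x2 table")
    a, b, c, d = (int(v) for v in cells)
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orr), float(p)


@dataclass
class GOCluster:
    """A connected component of redundant GO terms."""

    members: tuple
    representative: str


def _go_sets(annotation: pd.DataFrame) -> dict:
    return {go: set(sub["gene"]) for go, sub in annotation.groupby("go_id")}


def go_enrichment(
    cluster_genes,
    annotation: pd.DataFrame,
    background=None,
    min_de_in_go: int = 5,
    cluster_label=None,
    include_unannotated: bool = False,
) -> pd.DataFrame:
    """Fisher overrepresentation of GO terms in one gene cluster.

    Parameters
    ----------
    cluster_genes
        The DE genes of one expression cluster.
    annotation
        Long table with columns ``gene`` and ``go_id``.
    background
        The gene universe; defaults to all annotated genes (set
        ``include_unannotated`` to keep unannotated background genes in
        the totals instead).
    min_de_in_go
        A GO term is tested only when it contains strictly more than
        this many cluster genes.

    Returns a DataFrame with the 2x2 counts, ``(a/|GO|)`` display label,
    odds ratio, p and BH q per tested GO term.
    """
    annotated = set(annotation["gene"])
    if background is None:
        background = annotated
    else:
        background = set(background)
        if not set(cluster_genes) <= background:
            raise ValueError("background must contain the cluster genes")
    if not include_unannotated:
        background = background & annotated
    # unannotated cluster genes count only via include_unannotated totals
    cluster = set(cluster_genes) & background

    rows = []
    for go, genes in _go_sets(annotation).items():
        genes = genes & background
        a = len(cluster & genes)
        if a <= min_de_in_go:
            continue
        b = len(genes) - a
        c = len(cluster) - a
        d = len(background) - a - b - c
        orr, p = fisher_2x2(a, b, c, d)
        rows.append(
            {
                "cluster": cluster_label,
                "go_id": go,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "go_size": len(genes),
                "label": f"({a}/{len(genes)})",
                "odds_ratio": orr,
                "pvalue": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "go_id",
            "a",
            "b",
            "c",
            "d",
            "go_size",
            "label",
            "odds_ratio",
            "pvalue",
        ],
    )
    result["qvalue"] = bh_adjust(result["pvalue"].to_numpy()) if len(result) else []
    return result


def overlap_coefficient(set_a: set, set_b: set) -> float:
    """|A ∩ B| / min(|A|, |B|); 1 when one set contains the other."""
    if not set_a or not set_b:
        return 0.0
    return len(set_a & set_b) / min(len(set_a), len(set_b))


def collapse_redundant(
    records: pd.DataFrame, annotation: pd.DataFrame, threshold: float = 0.8
) -> list[GOCluster]:
    """Cluster redundant GO terms among the supplied enrichment records.

    Builds a graph over the records' GO ids with an edge whenever the
    overlap coefficient of the *full* GO gene sets exceeds ``threshold``;
    connected components become GOClusters. The representative is the
    member with the smallest q (ties: largest OR, then lexicographic id).
    """
    if len(records) == 0:
        raise ValueError("no enrichment records to collapse")
    sets = _go_sets(annotation)
    ids = list(records["go_id"])
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, gi in enumerate(ids):
        for gj in ids[i + 1 :]:
            if overlap_coefficient(sets.get(gi, set()), sets.get(gj, set())) > threshold:
                g.add_edge(gi, gj)
    by_id = records.set_index("go_id")
    clusters = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        ranked = sorted(
            members,
            key=lambda go: (
                by_id.loc[go, "qvalue"],
                -by_id.loc[go, "odds_ratio"],
                go,
            ),
        )
        clusters.append(GOCluster(members=members, representative=ranked[0]))
    clusters.sort(key=lambda c: c.representative)
    return clusters
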