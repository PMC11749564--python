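"""Cross-study comparison of in situ clusters with in vitro crossing DE.

In situ expression clusters are tested for association with the gene
sets found up- or down-regulated during in vitro sexual-reproduction
(crossing) experiments at three timepoints: one hour (T1), 24 hours
(T2), and five days (T3) after mixing opposite mating types. The
universe is the set of in situ genes with at least one mapped in vitro
homolog; a gene carries a direction@timepoint label when any of its
homologs does (against either the MT+ or MT- cross). Discordant genes —
members of a cluster whose mean in vitro log2FC opposes the cluster's
in situ trend — are extracted for secondary enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TIMEPOINTS, HomologyPanel
from .enrichment import fisher_2x2


class NoMappedGenesError(ValueError):
    """Raised when the homology panel maps no genes."""


@dataclass
class CrossEnrichment:
    """2x2 association of one cluster set with one in vitro label."""

    label: str
    timepoint: str
    direction: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    pvalue: float

    @property
    def table(self) -> tuple:
        return (self.a, self.b, self.c, self.d)


def _labeled_genes(panel: HomologyPanel, timepoint: str, direction: str) -> set:
    """In situ genes with >=1 homolog carrying ``direction`` at ``timepoint``."""
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    lab = panel.labels
    hit_invitro = set(
        lab.loc[(lab["timepoint"] == timepoint) & (lab["direction"] == direction), "invitro_gene"]
    )
    hom = panel.homology.drop_duplicates()
    return set(hom.loc[hom["invitro_gene"].isin(hit_invitro), "insitu_gene"])


def cross_enrich(
    cluster_set,
    panel: HomologyPanel,
    timepoint: str,
    direction: str,
    label: str = "",
) -> CrossEnrichment:
    """Fisher association between a cluster gene set and an in vitro label.

    Universe: in situ genes with a mapped homolog. Row factor: cluster
    membership; column factor: carrying the (direction, timepoint) label
    via any homolog.
    """
    universe = panel.mapped_universe()
    if not universe:
        raise NoMappedGenesError("no mapped genes in the homology panel")
    cluster = set(cluster_set) & universe
    if not cluster:
        raise NoMappedGenesError(
            f"cluster set {label or '<unnamed>'} shares no genes with the mapped universe"
        )
    labeled = _labeled_genes(panel, timepoint, direction)
    a = len(cluster & labeled)
    b = len(cluster - labeled)
    c = len(labeled - cluster)
    d = len(universe) - a - b - c
    orr, p = fisher_2x2(a, b, c, d)
    return CrossEnrichment(label, timepoint, direction, a, b, c, d, orr, p)


def cross_enrich_all(cluster_sets: dict, panel: HomologyPanel) -> pd.DataFrame:
    """All (cluster set, timepoint, direction) Fisher associations."""
    rows = []
    for label, genes in cluster_sets.items():
        for tp in TIMEPOINTS:
            for direction in ("up", "down"):
                try:
                    ce = cross_enrich(genes, panel, tp, direction, label=label)
                except NoMappedGenesError:
                    continue
                rows.append(
                    {
                        "label": label,
                        "timepoint": tp,
                        "direction": direction,
                        "a": ce.a,
                        "b": ce.b,
                        "c": ce.c,
                        "d": ce.d,
                        "odds_ratio": ce.odds_ratio,
                        "pvalue": ce.pvalue,
                    }
                )
    out = pd.DataFrame(rows)
    if len(out):
        from .de import bh_adjust

        out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def discordant_genes(
    cluster_set,
    panel: HomologyPanel,
    insitu_direction: str,
    timepoints=TIMEPOINTS,
) -> set:
    """Cluster genes whose mean in vitro log2FC opposes the in situ trend.

    For a cluster down-regulated in situ (``insitu_direction='down'``),
    the discordant genes are those with average homolog log2FC (over the
    stated timepoints and both crosses) strictly > 0, and conversely for
    up-regulated clusters. Genes without a homolog are excluded.
    """
    if insitu_direction not in ("up", "down"):
        raise ValueError("insitu_direction must be 'up' or 'down'")
    lab = panel.labels[panel.labels["timepoint"].isin(set(timepoints))]
    merged = panel.homology.merge(lab, on="invitro_gene")
    merged = merged[merged["insitu_gene"].isin(set(cluster_set))]
    if not len(merged):
        return set()
    means = (
        pd.concat(
            [
                merged[["insitu_gene", "vs_plus_log2fc"]].rename(columns={"vs_plus_log2fc": "lfc"}),
                merged[["insitu_gene", "vs_minus_log2fc"]].rename(columns={"vs_minus_log2fc": "lfc"}),
            ]
        )
        .groupby("insitu_gene")["lfc"]
        .mean()
    )
    if insitu_direction == "down":
        return set(means.index[means > 0])
    return set(means.index[means < 0])


def marker_report(log2fc: pd.DataFrame, marker_map: dict) -> pd.DataFrame:
    """Per-marker log2FC trajectory table across days.

    ``marker_map`` maps marker names to gene ids; markers missing from
    the expression matrix are flagged as not expressed (their trajectory
    is NaN).
    """
    rows = []
    for name, gene in marker_map.items():
        if gene in log2fc.index:
            traj = log2fc.loc[gene]
            rows.append(
                {
                    "marker": name,
                    "gene": gene,
                    "status": "expressed",
                    "peak_day": traj.idxmax(),
                    "peak_log2fc": float(traj.max()),
                    **{str(day): float(v) for day, v in traj.items()},
                }
            )
        else:
            rows.append(
                {
                    "marker": name,
                    "gene": gene,
                    "status": "not expressed",
                    "peak_day": None,
                    "peak_log2fc": np.nan,
                    **{str(day): np.nan for day in log2fc.columns},
                }
            )
    return pd.DataFrame(rows)
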