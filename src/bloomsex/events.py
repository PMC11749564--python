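"""Transient over-expression event detection and the evidence report.

A synchronized sexualization event shows up as a cluster whose log2FC
profile peaks sharply on a single sampling day and is otherwise flat.
The detector formalizes "transient" explicitly (the criterion is a
stand-in for visual identification and is labelled as such in the
report): the profile's maximum must exceed both adjacent sampling days
by at least ``delta`` log2 units, and all non-peak days must stay
within ±delta/2 of their own median. The combined verdict requires the
transient cluster, at least one sexualization marker gene inside it,
and a significant cross-study T1-up association.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_DELTA = 1.0


@dataclass
class TransientDetection:
    cluster: object | None
    peak_day: object | None
    score: float
    scores: dict = field(default_factory=dict)

    @property
    def found(self) -> bool:
        return self.cluster is not None


def transience_score(profile: np.ndarray) -> tuple[float, int, bool, float]:
    """(peak minus best neighbor, peak index, flatness flag raw data).

    Returns the margin by which the peak exceeds its adjacent sampling
    days, the peak's index, whether the profile has >= 3 points, and the
    maximum deviation of non-peak days from their median.
    """
    p = np.asarray(profile, float)
    i = int(p.argmax())
    neighbors = [p[i - 1]] if i > 0 else []
    if i + 1 < len(p):
        neighbors.append(p[i + 1])
    margin = float(p[i] - max(neighbors)) if neighbors else 0.0
    rest = np.delete(p, i)
    flat_dev = float(np.abs(rest - np.median(rest)).max()) if len(rest) else 0.0
    return margin, i, len(p) >= 3, flat_dev


def detect_transient_cluster(profiles: pd.DataFrame, delta: float = DEFAULT_DELTA) -> TransientDetection:
    """Find the highest-scoring single-day transient cluster, if any.

    ``profiles`` is the fitted cluster x day log2FC-effect matrix
    (adjacent columns are adjacent observed sampling days). A cluster is
    transient iff its peak exceeds both neighboring days by >= delta and
    every non-peak day sits within ±delta/2 of the non-peak median.
    """
    best = TransientDetection(None, None, -np.inf)
    scores = {}
    for k, row in profiles.iterrows():
        margin, i, ok, flat_dev = transience_score(row.to_numpy())
        scores[k] = margin
        if not ok:
            continue
        if margin >= delta and flat_dev <= delta / 2.0:
            if margin > best.score:
                best = TransientDetection(k, profiles.columns[i], margin)
    best.scores = scores
    if not best.found:
        best.score = float("nan")
    return best


def assemble_report(
    detection: TransientDetection,
    assignments: pd.Series | None,
    marker_table: pd.DataFrame | None,
    cross_enrichments: pd.DataFrame | None,
    enrichment: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Combine the evidence into the sexual-reproduction event report.

    Verdict is true iff (i) a transient cluster was found, (ii) at least
    one marker gene belongs to it, and (iii) the cross-study T1-up
    association for that cluster is significant at q <= alpha. The three
    sub-flags are reported individually; the verdict is monotone in the
    evidence.
    """
    report: dict = {
        "transience_criterion": "explicit stand-in: single-day peak >= delta over neighbors, "
        "non-peak days within +/- delta/2 of their median",
        "transient_cluster_found": bool(detection.found),
        "transient_cluster": None if not detection.found else detection.cluster,
        "peak_day": None if not detection.found else str(detection.peak_day),
        "transience_scores": {str(k): float(v) for k, v in detection.scores.items()},
    }

    markers_in_cluster: list = []
    if detection.found and assignments is not None and marker_table is not None:
        member_genes = set(assignments.index[assignments == detection.cluster])
        expressed = marker_table[marker_table["status"] == "expressed"]
        markers_in_cluster = sorted(
            expressed.loc[expressed["gene"].isin(member_genes), "marker"]
        )
    report["markers_in_transient_cluster"] = markers_in_cluster
    report["marker_evidence"] = len(markers_in_cluster) > 0
    if marker_table is not None:
        report["missing_markers"] = sorted(
            marker_table.loc[marker_table["status"] == "not expressed", "marker"]
        )

    t1_up_significant = False
    t1_up = None
    if detection.found and cross_enrichments is not None and len(cross_enrichments):
        qcol = "qvalue" if "qvalue" in cross_enrichments.columns else "pvalue"
        sub = cross_enrichments[
            (cross_enrichments["label"].astype(str) == str(detection.cluster))
            & (cross_enrichments["timepoint"] == "T1")
            & (cross_enrichments["direction"] == "up")
        ]
        if len(sub):
            row = sub.iloc[0]
            t1_up = {
                "odds_ratio": float(row["odds_ratio"]),
                "pvalue": float(row["pvalue"]),
                "qvalue": float(row[qcol]),
            }
            t1_up_significant = bool(row[qcol] <= alpha)
    report["cross_study_t1_up"] = t1_up
    report["cross_study_evidence"] = t1_up_significant

    if enrichment is not None and len(enrichment) and detection.found:
        sub = enrichment[enrichment["cluster"].astype(str) == str(detection.cluster)]
        report["transient_cluster_go_terms"] = sub["go_id"].tolist()

    report["sexual_reproduction_signal"] = bool(
        report["transient_cluster_found"]
        and report["marker_evidence"]
        and report["cross_study_evidence"]
    )
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=str)
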