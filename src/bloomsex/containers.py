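"""Shared in-memory containers for the bloom analysis pipeline.

The pipeline moves three kinds of tabular data around: gene-by-sample
integer count matrices with their sample sheets, per-sample taxon
relative-abundance tables, and the homology panel linking in situ genes
to in vitro crossing-experiment genes with their differential-expression
labels. These are thin, validated wrappers around pandas objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIMEPOINTS = ("T1", "T2", "T3")
DIRECTIONS = ("up", "down", "ns")


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts plus a sample sheet.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id.
    samples
        Sample sheet indexed by sample id with columns ``day``,
        ``replicate`` and optionally ``group``. Every count column must
        appear in the sheet.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("count matrix contains negative entries")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        if "day" not in self.samples.columns:
            raise ValueError("sample sheet must carry a 'day' column")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def days(self) -> list:
        """Day labels in order of first appearance in the sample sheet."""
        sheet = self.samples.loc[self.counts.columns]
        return list(pd.unique(sheet["day"]))

    def subset_samples(self, sample_ids) -> "CountMatrix":
        keep = [s for s in self.counts.columns if s in set(sample_ids)]
        return CountMatrix(self.counts[keep], self.samples.loc[keep])

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.samples)


@dataclass
class AbundanceTable:
    """Per-sample taxon fractions plus the assigned-read denominator.

    ``fractions`` rows sum to 1 for every sample with at least one
    taxonomically assigned read; samples with none get an all-zero row
    and are listed in ``warnings``.
    """

    fractions: pd.DataFrame  # samples x taxa
    assigned_read_count: pd.Series  # per sample
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = self.assigned_read_count > 0
        if pos.any():
            sums = self.fractions.loc[pos.index[pos]].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("per-sample fractions do not sum to 1")


@dataclass
class HomologyPanel:
    """In situ <-> in vitro homology map with per-timepoint DE labels.

    ``homology`` holds (insitu_gene, invitro_gene) pairs; ``labels``
    is long-format with one row per (invitro_gene, timepoint) carrying a
    direction in {up, down, ns} and signed log2 fold changes of the
    cross against the MT+ and MT- parental strains.
    """

    homology: pd.DataFrame  # columns: insitu_gene, invitro_gene
    labels: pd.DataFrame  # columns: invitro_gene, timepoint, vs_plus_log2fc, vs_minus_log2fc, direction

    def __post_init__(self) -> None:
        need = {"insitu_gene", "invitro_gene"}
        if not need.issubset(self.homology.columns):
            raise ValueError("homology table needs insitu_gene and invitro_gene columns")
        need = {"invitro_gene", "timepoint", "vs_plus_log2fc", "vs_minus_log2fc", "direction"}
        if not need.issubset(self.labels.columns):
            raise ValueError(f"label table needs columns {sorted(need)}")
        bad_tp = set(self.labels["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints {sorted(bad_tp)}")
        bad_dir = set(self.labels["direction"]) - set(DIRECTIONS)
        if bad_dir:
            raise ValueError(f"unknown directions {sorted(bad_dir)}")

    def mapped_universe(self) -> set:
        """In situ genes with at least one mapped in vitro homolog."""
        return set(self.homology["insitu_gene"].unique())

    def is_empty(self) -> bool:
        return len(self.homology) == 0
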