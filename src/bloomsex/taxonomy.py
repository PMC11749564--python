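"""Consensus minimum-e-value taxonomic assignment and relative abundances.

A read is assigned at a given rank only when *all* of its hits sharing
the read's minimum e-value agree on the taxon at that rank and the
minimum e-value passes the database-specific threshold (1e-70 for
class-level 18S searches, 1e-30 for genus/species rbcL searches).
Relative abundances divide per-taxon read counts by the total number of
taxonomically assigned reads in each sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AbundanceTable
from .simulate import OUTFMT6_COLUMNS

UNASSIGNED = "unassigned"

#: Database-specific consensus e-value ceilings.
EVALUE_MAX_18S_CLASS = 1e-70
EVALUE_MAX_RBCL = 1e-30

DEFAULT_RANKS = ("class", "genus", "species")


class TaxonomyMap:
    """subject_id -> ordered lineage (rank -> taxon name)."""

    def __init__(self, lineages: pd.DataFrame, ranks: tuple = DEFAULT_RANKS):
        """``lineages`` has columns subject_id and lineage (';'-joined, one
        field per rank, ordered as ``ranks``)."""
        self.ranks = tuple(ranks)
        split = lineages["lineage"].str.split(";")
        bad = split.map(len) != len(self.ranks)
        if bad.any():
            raise ValueError(
                f"lineages with wrong number of ranks: {lineages.loc[bad, 'subject_id'].tolist()[:5]}"
            )
        self._table = pd.DataFrame(
            split.tolist(), columns=list(self.ranks), index=lineages["subject_id"].values
        )

    def taxon_at(self, subject_ids: pd.Series, rank: str) -> pd.Series:
        if rank not in self.ranks:
            raise ValueError(f"rank {rank!r} not in {self.ranks}")
        missing = sorted(set(subject_ids) - set(self._table.index))
        if missing:
            raise KeyError(f"subject ids absent from taxonomy map: {missing[:10]}")
        return pd.Series(
            self._table[rank].reindex(subject_ids.values).values, index=subject_ids.index
        )


def read_hits(path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt 6) file, with or without a header line."""
    with open(path) as fh:
        first_field = ""
        for line in fh:
            if not line.startswith("#"):
                first_field = line.split("\t", 1)[0]
                break
    has_header = first_field == "qseqid"
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=0 if has_header else None,
        names=None if has_header else list(OUTFMT6_COLUMNS),
    )
    return df


def read_taxmap(path, ranks: tuple = DEFAULT_RANKS) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "subject_id" not in df.columns:  # headerless fallback
        df = pd.read_csv(path, sep="\t", header=None, names=["subject_id", "lineage"])
    return TaxonomyMap(df, ranks=ranks)


def assign_reads(
    hits: pd.DataFrame,
    taxmap: TaxonomyMap,
    rank: str,
    evalue_max: float = EVALUE_MAX_18S_CLASS,
) -> pd.Series:
    """Consensus assignment: per read, the full set of hits tied at the
    minimum e-value must agree at ``rank`` and pass ``evalue_max``.

    Returns a read_id -> taxon Series, with ``'unassigned'`` for reads
    failing either condition. E-value ties are exact comparisons of the
    parsed decimal values; bitscores never break ties.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    if (hits["evalue"] < 0).any():
        raise ValueError("negative e-values in hit table")
    df = hits[["qseqid", "sseqid", "evalue"]].copy()
    df["taxon"] = taxmap.taxon_at(df["sseqid"], rank)
    min_e = df.groupby("qseqid")["evalue"].transform("min")
    tied = df[df["evalue"] == min_e]
    per_read = tied.groupby("qseqid").agg(
        n_taxa=("taxon", "nunique"), taxon=("taxon", "first"), evalue=("evalue", "first")
    )
    ok = (per_read["n_taxa"] == 1) & (per_read["evalue"] <= evalue_max)
    out = per_read["taxon"].where(ok, UNASSIGNED)
    out.index.name = "read_id"
    out.name = "taxon"
    return out


def sample_of_read(read_ids: pd.Index) -> pd.Series:
    """Sample id encoded as the prefix of ``<sample>.<number>`` read ids."""
    return pd.Series(read_ids.str.rsplit(".", n=1).str[0].values, index=read_ids)


def relative_abundance(assignments: pd.Series, samples: pd.Series) -> AbundanceTable:
    """Per-sample taxon fractions over taxonomically assigned reads.

    ``samples`` maps each read id to its sample; unassigned reads are
    excluded from the denominator. Samples with zero assigned reads get
    an all-zero row and a warning record.
    """
    df = pd.DataFrame({"taxon": assignments, "sample": samples.reindex(assignments.index)})
    if df["sample"].isna().any():
        raise ValueError("reads without a sample mapping")
    assigned = df[df["taxon"] != UNASSIGNED]
    counts = (
        assigned.groupby(["sample", "taxon"]).size().unstack(fill_value=0)
        if len(assigned)
        else pd.DataFrame()
    )
    all_samples = pd.Index(pd.unique(df["sample"]), name="sample")
    counts = counts.reindex(index=all_samples, fill_value=0)
    if counts.shape[1] == 0:
        counts = pd.DataFrame(index=all_samples)
    totals = counts.sum(axis=1) if counts.shape[1] else pd.Series(0, index=all_samples)
    fractions = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    warnings = [f"sample {s}: zero assigned reads" for s in all_samples[totals == 0]]
    return AbundanceTable(
        fractions=fractions, assigned_read_count=totals.astype(int), warnings=warnings
    )


def exclude_low_focal_samples(
    abundance: AbundanceTable, focal_taxon: str, min_fraction: float = 0.05
) -> list:
    """Samples whose focal-taxon fraction is below ``min_fraction``.

    These are the samples to drop from expression analysis (the survey
    excluded its final sampling day for exactly this reason). The 0.05
    default is a configuration value, not an observed constant.
    """
    if focal_taxon not in abundance.fractions.columns:
        if min_fraction <= 0:
            return []
        raise KeyError(f"focal taxon {focal_taxon!r} absent from abundance table")
    frac = abundance.fractions[focal_taxon]
    return list(frac.index[frac < min_fraction])
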