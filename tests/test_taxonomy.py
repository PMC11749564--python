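"""Consensus assignment and relative-abundance tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloomsex.taxonomy import (
    TaxonomyMap,
    UNASSIGNED,
    assign_reads,
    exclude_low_focal_samples,
    relative_abundance,
    sample_of_read,
)
from oracles import assign_reads_enumeration


def _taxmap(subject_taxon: dict) -> TaxonomyMap:
    df = pd.DataFrame(
        {
            "subject_id": list(subject_taxon),
            "lineage": [f"{t};{t}_g;{t}_g_sp" for t in subject_taxon.values()],
        }
    )
    return TaxonomyMap(df)


def _hits(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue"])


class TestAssignReads:
    def test_tie_between_taxa_is_unassigned(self):
        tm = _taxmap({"s1": "classX", "s2": "classY"})
        hits = _hits([("r1", "s1", 1e-80), ("r1", "s2", 1e-80)])
        assert assign_reads(hits, tm, "class", 1e-70)["r1"] == UNASSIGNED

    def test_single_good_hit_assigned(self):
        tm = _taxmap({"s1": "classX"})
        hits = _hits([("r1", "s1", 1e-80)])
        assert assign_reads(hits, tm, "class", 1e-70)["r1"] == "classX"

    def test_min_evalue_above_threshold_unassigned(self):
        tm = _taxmap({"s1": "classX"})
        hits = _hits([("r1", "s1", 1e-50)])
        assert assign_reads(hits, tm, "class", 1e-70)["r1"] == UNASSIGNED

    def test_agreeing_tie_with_weaker_disagreeing_hit_assigned(self):
        tm = _taxmap({"s1": "classX", "s2": "classX", "s3": "classY"})
        hits = _hits(
            [("r1", "s1", 1e-90), ("r1", "s2", 1e-90), ("r1", "s3", 1e-75)]
        )
        assert assign_reads(hits, tm, "class", 1e-70)["r1"] == "classX"

    def test_missing_subject_raises_with_ids(self):
        tm = _taxmap({"s1": "classX"})
        hits = _hits([("r1", "sX", 1e-90)])
        with pytest.raises(KeyError, match="sX"):
            assign_reads(hits, tm, "class", 1e-70)

    def test_matches_enumeration_oracle_on_randomized_table(self):
        rng = np.random.default_rng(0)
        taxa = ["A", "B", "C"]
        subject_taxon = {f"s{i}": taxa[i % 3] for i in range(9)}
        tm = _taxmap(subject_taxon)
        rows = []
        for r in range(400):
            for _ in range(rng.integers(1, 5)):
                ev = float(10.0 ** rng.integers(-90, -50)) * rng.choice([1, 1, 10])
                rows.append((f"r{r:04d}", f"s{rng.integers(9)}", ev))
        hits = _hits(rows)
        got = assign_reads(hits, tm, "class", 1e-70)
        want = assign_reads_enumeration(rows, subject_taxon, 1e-70)
        assert got.to_dict() == want

    def test_row_order_invariance_and_evalue_monotonicity(self):
        rng = np.random.default_rng(1)
        subject_taxon = {f"s{i}": "AB"[i % 2] for i in range(4)}
        tm = _taxmap(subject_taxon)
        rows = [
            (f"r{r}", f"s{rng.integers(4)}", float(10.0 ** rng.integers(-90, -55)))
            for r in range(200)
            for _ in range(rng.integers(1, 4))
        ]
        hits = _hits(rows)
        shuffled = hits.sample(frac=1.0, random_state=2)
        a = assign_reads(hits, tm, "class", 1e-70)
        b = assign_reads(shuffled, tm, "class", 1e-70)
        assert a.sort_index().equals(b.sort_index())
        n_assigned = [
            (assign_reads(hits, tm, "class", emax) != UNASSIGNED).sum()
            for emax in (1e-80, 1e-70, 1e-60)
        ]
        assert n_assigned == sorted(n_assigned)


class TestRelativeAbundance:
    def test_simple_fractions(self):
        asg = pd.Series(
            ["A"] * 7 + ["B"] * 3, index=[f"s1.{i:06d}" for i in range(10)], name="taxon"
        )
        table = relative_abundance(asg, sample_of_read(asg.index))
        assert table.fractions.loc["s1", "A"] == pytest.approx(0.7)
        assert table.fractions.loc["s1", "B"] == pytest.approx(0.3)
        assert table.assigned_read_count["s1"] == 10

    def test_all_unassigned_gives_empty_row_and_warning(self):
        asg = pd.Series([UNASSIGNED] * 5, index=[f"s1.{i:06d}" for i in range(5)])
        table = relative_abundance(asg, sample_of_read(asg.index))
        assert table.assigned_read_count["s1"] == 0
        assert any("s1" in w for w in table.warnings)

    def test_fractions_sum_to_one_per_assigned_sample(self):
        rng = np.random.default_rng(3)
        reads = [f"s{j}.{i:06d}" for j in range(3) for i in range(50)]
        asg = pd.Series(rng.choice(["A", "B", UNASSIGNED], len(reads)), index=pd.Index(reads))
        table = relative_abundance(asg, sample_of_read(asg.index))
        pos = table.assigned_read_count > 0
        assert np.allclose(table.fractions[pos.values].sum(axis=1), 1.0, atol=1e-9)


class TestExcludeLowFocal:
    @staticmethod
    def _abundance(fracs: dict):
        asg_counts = pd.Series({s: 100 for s in fracs})
        df = pd.DataFrame({"focal": pd.Series(fracs)})
        df["other"] = 1.0 - df["focal"]
        from bloomsex.containers import AbundanceTable

        return AbundanceTable(df, asg_counts)

    def test_zero_threshold_excludes_nothing(self):
        ab = self._abundance({"s1": 0.5, "s2": 0.0})
        assert exclude_low_focal_samples(ab, "focal", 0.0) == []

    def test_threshold_filters(self):
        ab = self._abundance({"s1": 0.5, "s2": 0.05})
        assert exclude_low_focal_samples(ab, "focal", 0.1) == ["s2"]

    @settings(deadline=None, max_examples=25)
    @given(
        fracs=st.lists(st.floats(0, 1), min_size=1, max_size=8),
        thr=st.floats(0, 1),
    )
    def test_matches_direct_filter(self, fracs, thr):
        ab = self._abundance({f"s{i}": f for i, f in enumerate(fracs)})
        got = set(exclude_low_focal_samples(ab, "focal", thr))
        want = {f"s{i}" for i, f in enumerate(fracs) if f < thr}
        assert got == want
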