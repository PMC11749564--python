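"""Fisher exact, GO overrepresentation, redundancy collapse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloomsex.enrichment import (
    collapse_redundant,
    fisher_2x2,
    go_enrichment,
    overlap_coefficient,
)
from oracles import fisher_two_sided_enumeration, transitive_closure_components


class TestFisher2x2:
    def test_independence_table(self):
        orr, p = fisher_2x2(10, 10, 10, 10)
        assert orr == 1.0 and p == 1.0

    def test_diagonal_table_exact_value(self):
        _, p = fisher_2x2(5, 0, 0, 5)
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        orr, _ = fisher_2x2(5, 0, 0, 5)
        assert orr == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))
        orr2, _ = fisher_2x2(4, 2, 1, 8)
        assert orr2 == pytest.approx(32 / 2)  # no correction when all cells > 0

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(0, 0, 0, 0)

    @settings(deadline=None, max_examples=60)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12), c=st.integers(0, 12), d=st.integers(0, 12)
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        _, p = fisher_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_two_sided_enumeration(a, b, c, d), rel=1e-10, abs=1e-14)

    @settings(deadline=None, max_examples=30)
    @given(a=st.integers(0, 15), b=st.integers(0, 15), c=st.integers(0, 15), d=st.integers(0, 15))
    def test_symmetric_under_simultaneous_row_and_column_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        _, p1 = fisher_2x2(a, b, c, d)
        _, p2 = fisher_2x2(d, c, b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)


def _annotation(sets: dict) -> pd.DataFrame:
    rows = [(g, go) for go, genes in sets.items() for g in genes]
    return pd.DataFrame(rows, columns=["gene", "go_id"])


class TestGOEnrichment:
    def test_minimum_size_rule_is_strict(self):
        # GO with exactly 5 cluster genes is skipped ("more than five")
        sets = {"GO:A": [f"g{i}" for i in range(5)] + ["h1", "h2"]}
        ann = _annotation(sets)
        ann = pd.concat(
            [ann, pd.DataFrame({"gene": [f"b{i}" for i in range(30)], "go_id": "GO:B"})]
        )
        cluster = [f"g{i}" for i in range(5)]
        assert len(go_enrichment(cluster, ann, min_de_in_go=5)) == 0

    def test_enriched_term_detected_with_counts_label(self):
        cluster = [f"g{i}" for i in range(10)]
        background_genes = [f"b{i}" for i in range(200)]
        sets = {
            "GO:HIT": cluster[:8] + background_genes[:10],
            "GO:BG": background_genes[50:190],
        }
        ann = _annotation(sets)
        # give every gene an annotation so the universe covers them
        ann = pd.concat([ann, pd.DataFrame({"gene": cluster + background_genes, "go_id": "GO:ALL"})])
        rec = go_enrichment(cluster, ann, min_de_in_go=5)
        hit = rec[rec["go_id"] == "GO:HIT"].iloc[0]
        assert hit["a"] == 8 and hit["label"] == "(8/18)"
        assert hit["odds_ratio"] > 1 and hit["qvalue"] < 0.05
        # enlarging the cluster can only increase a
        rec2 = go_enrichment(cluster + background_genes[:5], ann, min_de_in_go=5)
        assert rec2[rec2["go_id"] == "GO:HIT"].iloc[0]["a"] >= 8

    def test_no_term_passes_size_rule_gives_empty_frame(self):
        ann = _annotation({"GO:A": ["g1", "g2"]})
        rec = go_enrichment(["g1"], ann)
        assert len(rec) == 0

    def test_background_must_contain_cluster(self):
        ann = _annotation({"GO:A": ["g1", "g2"]})
        with pytest.raises(ValueError):
            go_enrichment(["g1", "zz"], ann, background=["g1", "g2"])


class TestCollapseRedundant:
    @staticmethod
    def _records(go_ids):
        return pd.DataFrame(
            {
                "go_id": go_ids,
                "qvalue": np.linspace(0.001, 0.04, len(go_ids)),
                "odds_ratio": np.linspace(5, 2, len(go_ids)),
            }
        )

    def test_subset_pair_co_clusters(self):
        ann = _annotation({"GO:A": ["g1", "g2", "g3", "g4"], "GO:B": ["g1", "g2"]})
        comps = collapse_redundant(self._records(["GO:A", "GO:B"]), ann, 0.8)
        assert len(comps) == 1
        assert comps[0].members == ("GO:A", "GO:B")
        assert comps[0].representative == "GO:A"  # smallest q wins

    def test_overlap_two_thirds_stays_separate(self):
        ann = _annotation({"GO:A": ["a", "b", "c"], "GO:B": ["b", "c", "d"]})
        assert overlap_coefficient({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(2 / 3)
        comps = collapse_redundant(self._records(["GO:A", "GO:B"]), ann, 0.8)
        assert len(comps) == 2

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            collapse_redundant(pd.DataFrame(), _annotation({"GO:A": ["g"]}), 0.8)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        sets = {
            f"GO:{j}": list(rng.choice(genes, size=rng.integers(2, 12), replace=False))
            for j in range(8)
        }
        ann = _annotation(sets)
        comps = collapse_redundant(self._records(list(sets)), ann, 0.8)
        got = {frozenset(c.members) for c in comps}
        want = transitive_closure_components(
            list(sets), {k: set(v) for k, v in sets.items()}, 0.8
        )
        assert got == want
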