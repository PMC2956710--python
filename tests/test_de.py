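"""Exact count test, consistency rule, trend labels and the gene funnel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import ac_pvalue_oracle
from sagekit.de import (
    ACComparison,
    ac_pvalue,
    ac_tails,
    candidate_gene_summary,
    classify_trend,
    consistent_de,
    fdr_adjust,
    pairwise_de,
)
from sagekit.tagproc import TagCountTable, TagMap


class TestAcPvalue:
    def test_no_counts_no_evidence(self):
        assert ac_pvalue(0, 0, 1e5, 1e5) == 1.0
        assert ACComparison(0, 0, 10, 20).pvalue() == 1.0

    def test_matches_exact_oracle(self):
        # frozen spot values from the exact rational oracle
        assert float(ac_pvalue(5, 25, 10_000, 10_000)) == pytest.approx(
            float(ac_pvalue_oracle(5, 25, 10_000, 10_000)), rel=1e-10
        )
        for x, y, n1, n2 in [(0, 12, 250_000, 250_000), (3, 9, 10**5, 10**5),
                             (40, 50, 10**5, 2 * 10**5), (17, 2, 2 * 10**5, 10**5)]:
            assert float(ac_pvalue(x, y, n1, n2)) == pytest.approx(
                float(ac_pvalue_oracle(x, y, n1, n2)), rel=1e-10
            )

    @settings(derandomize=True, max_examples=120)
    @given(
        x=st.integers(0, 60), y=st.integers(0, 60),
        ratio=st.sampled_from([(1, 2), (1, 1), (2, 1)]),
    )
    def test_exchange_symmetry_and_bounds(self, x, y, ratio):
        n1, n2 = 10**5 * ratio[0], 10**5 * ratio[1]
        p = float(ac_pvalue(x, y, n1, n2))
        q = float(ac_pvalue(y, x, n2, n1))
        assert 0 < p <= 1
        assert p == pytest.approx(q, rel=1e-12)

    def test_monotone_away_from_conditional_mode(self):
        x, n1, n2 = 20, 10**5, 10**5
        ys = np.arange(0, 80)
        p = ac_pvalue(x, ys, n1, n2)
        mode = int(ys[np.argmax(p)])
        assert np.all(np.diff(p[ys >= mode]) <= 1e-12)
        assert np.all(np.diff(p[ys <= mode]) >= -1e-12)

    def test_tails_follow_conditional_definition(self):
        p_le, p_ge = ac_tails(3, 9, 10**5, 10**5)
        # tails overlap exactly at the boundary outcome
        assert float(p_le + p_ge) == pytest.approx(1 + 0.02685546875, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ac_pvalue(1, 1, 0, 10)
        with pytest.raises(ValueError):
            ac_pvalue(-1, 1, 10, 10)
        with pytest.raises(ValueError):
            ACComparison(1, 1, -5, 10)

    def test_type_i_error_conservative_under_null(self):
        rng = np.random.default_rng(42)
        lam, n = 20, 10**5
        x = rng.poisson(lam, size=10_000)
        y = rng.poisson(lam, size=10_000)
        frac = float(np.mean(ac_pvalue(x, y, n, n) <= 0.05))
        assert frac <= 0.06


def _lib(lib_id, counts):
    return TagCountTable(lib_id, counts)


class TestPairwiseDE:
    def test_self_comparison_rejected(self):
        a = _lib("A", {"T" * 17: 5})
        with pytest.raises(ValueError):
            pairwise_de(a, a, "A vs A")

    def test_identical_counts_never_significant(self):
        counts = {f"tag{i:013d}TTTT": 10 + i for i in range(20)}
        res = pairwise_de(_lib("A", counts), _lib("B", dict(counts)), "A vs B")
        assert (res["p"] > 0.05).all()
        assert (res["direction"] == "none").all()

    def test_planted_tenfold_change_significant(self):
        base = {f"t{i:015d}A": 100 for i in range(5)}
        a = dict(base)
        b = dict(base)
        a["P" * 17] = 100
        b["P" * 17] = 1000
        # pad library sizes to ~1e5
        a["F" * 17] = 10**5 - sum(a.values())
        b["F" * 17] = 10**5 - sum(b.values())
        res = pairwise_de(_lib("A", a), _lib("B", b), "A vs B")
        row = res[res["tag"] == "P" * 17].iloc[0]
        assert row["p"] < 0.001 and row["direction"] == "up"

    def test_absent_tag_enters_with_zero(self):
        a = {"A" * 17: 12, "F" * 17: 249_988}
        b = {"F" * 17: 250_000}
        res = pairwise_de(_lib("A", a), _lib("B", b), "A vs B")
        row = res[res["tag"] == "A" * 17].iloc[0]
        assert row["y"] == 0 and row["p"] <= 0.05 and row["direction"] == "down"

    def test_fdr_column_monotone_with_p(self):
        rng = np.random.default_rng(0)
        a = {f"t{i:016d}": int(c) for i, c in enumerate(rng.poisson(30, 50))}
        b = {f"t{i:016d}": int(c) for i, c in enumerate(rng.poisson(30, 50))}
        res = fdr_adjust(pairwise_de(_lib("A", a), _lib("B", b), "A vs B"))
        assert (res["q"] >= res["p"] - 1e-12).all()


def _de_frame(rows):
    return pd.DataFrame(
        rows, columns=["tag", "comparison", "replicate", "direction", "p"]
    )


class TestConsistency:
    def test_direction_conflict_excluded(self):
        frame = _de_frame([
            ("t1", "AS vs RAD", "r1", "up", 0.001),
            ("t1", "AS vs RAD", "r2", "up", 0.001),
            ("t1", "AS vs RAD", "r3", "down", 0.001),
        ])
        summary = consistent_de(frame)
        assert summary.n_consistent("AS vs RAD", "up", 0.05) == 0
        assert summary.n_consistent("AS vs RAD", "down", 0.05) == 0

    def test_all_replicates_same_direction_included(self):
        frame = _de_frame([
            ("t1", "AS vs RAD", r, "up", 0.004) for r in ("r1", "r2", "r3")
        ])
        summary = consistent_de(frame)
        assert summary.n_consistent("AS vs RAD", "up", 0.05) == 1
        assert summary.n_consistent("AS vs RAD", "up", 0.01) == 1
        assert summary.n_consistent("AS vs RAD", "up", 0.001) == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(200):
            for r in ("r1", "r2", "r3"):
                rows.append(
                    (f"t{i}", "RAD vs CR", r,
                     rng.choice(["up", "down"]), float(rng.uniform(0, 0.2)))
                )
        summary = consistent_de(_de_frame(rows))
        for direction in ("up", "down"):
            n = [summary.n_consistent("RAD vs CR", direction, a)
                 for a in (0.001, 0.01, 0.05)]
            assert n[0] <= n[1] <= n[2]

    def test_missing_replicate_detected(self):
        frame = _de_frame([
            ("t1", "AS vs RAD", "r1", "up", 0.01),
            ("t1", "RAD vs CR", "r1", "up", 0.01),
            ("t2", "RAD vs CR", "r2", "up", 0.01),
        ])
        with pytest.raises(ValueError, match="missing replicate"):
            consistent_de(frame)


class TestTrendLabels:
    def test_monotone_increase_is_group1(self):
        # e.g. a prostatic acid phosphatase-like profile 12 -> 79 -> 382
        label = classify_trend(
            "t", [(12, 79, 382), (7, 67, 136), (7, 52, 200)],
            [("up", True)] * 3, [("up", True)] * 3,
        )
        assert label.group == 1 and label.label == "A"

    def test_flat_profile_is_group4(self):
        label = classify_trend(
            "t", [(100, 100, 100)] * 3,
            [("none", False)] * 3, [("none", False)] * 3,
        )
        assert label.group == 4 and label.label == "M"

    def test_valley_at_middle_stage_is_group5(self):
        label = classify_trend(
            "t", [(500, 100, 480)] * 3,
            [("down", True)] * 3, [("up", True)] * 3,
        )
        assert label.group == 5 and label.label == "K"  # net slightly down

    def test_peak_is_group3(self):
        label = classify_trend(
            "t", [(100, 500, 120)] * 3,
            [("up", True)] * 3, [("down", True)] * 3,
        )
        assert label.group == 3

    def test_inconsistent_step_becomes_flat(self):
        label = classify_trend(
            "t", [(10, 30, 90)] * 3,
            [("up", True), ("up", True), ("down", True)],
            [("up", True)] * 3,
        )
        assert label.step1 == "flat" and label.group == 1

    def test_requires_three_stages(self):
        with pytest.raises(ValueError):
            classify_trend("t", [(1, 2)], [("up", True)], [("up", True)])


class TestFunnel:
    def _map(self):
        tmap = TagMap()
        spec = {
            "t1": ("unique_sense", [("G1", "+")]),
            "t2": ("unique_sense", [("G1", "+")]),     # same gene, 2 tags
            "t3": ("unique_sense", [("G2", "+")]),
            "t4": ("antisense", [("G3", "-")]),
            "t5": ("ambiguous", [("G4", "+"), ("G5", "+")]),
            "t6": ("host", []),
            "t7": ("no_map", []),
            "t8": ("genomic_only", []),
        }
        for tag, (cls, hits) in spec.items():
            tmap.mapping_class[tag] = cls
            tmap.hits[tag] = hits
        return tmap

    def test_counts_collapse_and_novelty(self):
        report = candidate_gene_summary(
            [f"t{i}" for i in range(1, 9)], self._map(), known_genes={"G2"}
        )
        assert report["n_input_tags"] == 8
        assert report["n_relevant"] == 6          # minus ambiguous + host
        assert report["n_candidate_genes"] == 3   # G1 (2 tags), G2, G3
        assert report["n_novel"] == 2             # G1, G3
        assert report["n_no_map"] == 1 and report["n_genomic_only"] == 1
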