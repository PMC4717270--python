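"""Annotation, summaries, change classification, correlation, enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from proturn import io, reporting


def fisher_greater_oracle(a, b, c, d):
    """Exact one-sided Fisher p by exhaustive hypergeometric tail enumeration.

    Table [[a, b], [c, d]]: hits/non-hits x in-set/out-of-set. Computed in
    exact rational arithmetic.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = math.comb(n, col1)
    total = Fraction(0)
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > n - row1:
            continue
        total += Fraction(math.comb(row1, k) * math.comb(n - row1, col1 - k), denom)
    return float(total)


class TestAnnotateCompartments:
    def test_assignment_and_precedence(self, caplog):
        with caplog.at_level("WARNING"):
            ann = reporting.annotate_compartments(
                ["A", "B", "C", "D"], mito_list=["A", "B"], cyto_list=["B", "C"]
            )
        comp = dict(zip(ann["protein_id"], ann["compartment"]))
        assert comp == {"A": "mito", "B": "mito", "C": "cyto", "D": "other"}
        assert any("both mito and cyto" in r.message for r in caplog.records)

    def test_empty_ids_empty_table(self):
        assert reporting.annotate_compartments([], ["A"], ["B"]).empty


class TestSummarizeHalfLives:
    @staticmethod
    def _fits(hls, prots=None, group="young"):
        return pd.DataFrame(
            {
                "protein_id": prots or [f"P{i}" for i in range(len(hls))],
                "group": group,
                "half_life_days": hls,
            }
        )

    def test_median_mean_count(self):
        ann = reporting.annotate_compartments(["P0", "P1", "P2"], [], [])
        out = reporting.summarize_half_lives(self._fits([10.0, 20.0, 30.0]), ann)
        total = out[(out["stratum"] == "total") & (out["group"] == "young")].iloc[0]
        assert total["median_t_half"] == 20.0
        assert total["mean_t_half"] == 20.0
        assert total["n_proteins"] == 3

    def test_single_fit(self):
        ann = reporting.annotate_compartments(["P0"], ["P0"], [])
        out = reporting.summarize_half_lives(self._fits([42.0]), ann)
        mito = out[(out["stratum"] == "mito")].iloc[0]
        assert mito["median_t_half"] == mito["mean_t_half"] == 42.0

    def test_empty_stratum_flagged(self):
        ann = reporting.annotate_compartments(["P0"], [], [])  # no mito at all
        out = reporting.summarize_half_lives(self._fits([10.0]), ann)
        mito = out[out["stratum"] == "mito"].iloc[0]
        assert mito["n_proteins"] == 0 and np.isnan(mito["median_t_half"])

    def test_median_invariant_to_ordering(self):
        ann = reporting.annotate_compartments([f"P{i}" for i in range(5)], [], [])
        fits = self._fits([50.0, 10.0, 30.0, 20.0, 40.0])
        a = reporting.summarize_half_lives(fits, ann)
        b = reporting.summarize_half_lives(
            fits.sample(frac=1.0, random_state=1), ann
        )
        pd.testing.assert_frame_equal(a, b)


class TestClassifyChanges:
    @staticmethod
    def _comparisons(sig_by_contrast):
        rows = []
        for contrast, directions in sig_by_contrast.items():
            for pid, direction in directions.items():
                rows.append(
                    {
                        "protein_id": pid,
                        "contrast": contrast,
                        "delta_alpha": {"longer_lived": 1.0, "shorter_lived": -1.0}.get(
                            direction, 0.001
                        ),
                        "p_value": 1e-8 if direction != "unchanged" else 0.9,
                        "q_value": 1e-6 if direction != "unchanged" else 0.9,
                    }
                )
        return pd.DataFrame(rows)

    def test_venn_set_algebra(self):
        comps = self._comparisons(
            {
                "m1": {p: "longer_lived" for p in "ABC"} | {"D": "unchanged"},
                "m2": {p: "longer_lived" for p in "BCD"} | {"A": "unchanged"},
            }
        )
        out = reporting.classify_changes(comps)
        venn = out["venn"]["m1|m2"]["longer_lived"]
        assert venn["tested_in_both"] == [1, 2, 1]
        assert venn["all_tested"] == [1, 2, 1]

    def test_all_non_significant_unchanged(self):
        comps = self._comparisons({"m1": {p: "unchanged" for p in "ABCD"}})
        out = reporting.classify_changes(comps)
        assert out["per_contrast"]["m1"]["unchanged"] == 4
        assert out["per_contrast"]["m1"]["longer_lived"] == 0

    def test_counts_partition_tested_set(self):
        comps = self._comparisons(
            {"m1": {"A": "longer_lived", "B": "shorter_lived", "C": "unchanged"}}
        )
        c = reporting.classify_changes(comps)["per_contrast"]["m1"]
        assert c["longer_lived"] + c["shorter_lived"] + c["unchanged"] == c["tested"]


class TestCorrelateChanges:
    def test_collinear_pairs(self):
        x = np.array([0.1, 0.4, -0.2, 0.9])
        out = reporting.correlate_changes(x, 2.0 * x + 0.3)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_independent_changes_mostly_uncorrelated(self):
        rng = np.random.default_rng(77)
        low = sum(
            reporting.correlate_changes(
                rng.normal(size=200), rng.normal(size=200)
            )["r_squared"] < 0.05
            for _ in range(20)
        )
        assert low >= 18  # r^2 < 0.05 in >= 90% of null replicates

    def test_insufficient_pairs(self):
        with pytest.raises(ValueError, match="insufficient pairs"):
            reporting.correlate_changes([0.1, 0.2], [0.3, 0.4])

    def test_degenerate_predictor(self):
        with pytest.raises(ValueError, match="degenerate predictor"):
            reporting.correlate_changes([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])


class TestEnrichGeneSets:
    def test_hit_set_equals_universe(self):
        universe = {f"g{i}" for i in range(20)}
        sets = {"s1": {f"g{i}" for i in range(10)}, "s2": set(universe)}
        out = reporting.enrich_gene_sets(universe, universe, sets)
        assert (out["fisher_p"] == 1.0).all()
        ratios = dict(zip(out["set_name"], out["overlap_ratio"]))
        assert ratios == {"s1": 1.0, "s2": 1.0}

    def test_fisher_matches_hypergeometric_oracle(self):
        # 2x2 table: 3 in-set hits, 7 in-set non-hits, 10 out-set hits,
        # 80 out-set non-hits
        universe = [f"g{i}" for i in range(100)]
        in_set = set(universe[:10])
        hits = set(universe[:3]) | set(universe[10:20])  # adjust to a=3,b=10
        out = reporting.enrich_gene_sets(hits, universe, {"s": in_set}, min_hits=1)
        expected = fisher_greater_oracle(3, 10, 7, 80)
        assert out["fisher_p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_sets_below_min_hits_excluded(self):
        universe = [f"g{i}" for i in range(30)]
        hits = set(universe[:5])
        sets = {"small": set(universe[:3]), "big": set(universe[:10])}
        out = reporting.enrich_gene_sets(hits, universe, sets)  # min_hits=4
        assert list(out["set_name"]) == ["big"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            reporting.enrich_gene_sets(set(), set(), {})

    def test_oracle_agreement_on_random_tables(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(60):
            a, b, c, d = rng.integers(0, 25, 4)
            p_scipy = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert p_scipy == pytest.approx(
                fisher_greater_oracle(int(a), int(b), int(c), int(d)), abs=1e-11
            )


class TestGmtIo:
    def test_roundtrip(self, tmp_path):
        sets = {"pathA": {"g1", "g2", "g3"}, "pathB": {"g2", "g4"}}
        path = io.write_gmt(sets, tmp_path / "sets.gmt")
        assert io.read_gmt(path) == sets

    def test_malformed_line_rejected(self, tmp_path):
        bad = tmp_path / "bad.gmt"
        bad.write_text("nameonly\tdesc\n")
        with pytest.raises(ValueError, match="GMT"):
            io.read_gmt(bad)

    def test_id_list_roundtrip(self, tmp_path):
        ids = {"P1", "P2", "P3"}
        path = io.write_id_list(ids, tmp_path / "mito.txt")
        assert io.read_id_list(path) == ids
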