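"""Stain-pair construction, Spearman oracle agreement and report I/O."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psrquant.stats import (
    ConsistencyReport,
    UndefinedCorrelationError,
    build_stain_pairs,
    method_consistency,
    read_score_table,
    reference_correlation,
    report_frames,
    spearman_rho,
    write_report,
    write_score_table,
)
from psrquant.synth import DEFAULT_LABORATORY_OF


def rank_definition_rho(x, y):
    """Independent oracle: Pearson correlation of explicit mid-ranks."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestBuildPairs:
    def test_four_sets_give_six_pairs(self):
        pairs = build_stain_pairs(["E1", "E2", "N1", "N2"], DEFAULT_LABORATORY_OF)
        assert len(pairs) == 6
        intra = {p for p, kind in pairs if kind == "intra"}
        assert intra == {("E1", "E2"), ("N1", "N2")}

    def test_two_sets_same_laboratory(self):
        pairs = build_stain_pairs(["E1", "E2"], {"E1": "E", "E2": "E"})
        assert pairs == [(("E1", "E2"), "intra")]

    def test_five_sets_with_rn3(self):
        pairs = build_stain_pairs(
            ["E1", "E2", "N1", "N2", "rN3"], DEFAULT_LABORATORY_OF
        )
        assert len(pairs) == 10
        assert sum(kind == "intra" for _, kind in pairs) == 4

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            build_stain_pairs(["E1", "E1"], {"E1": "E"})


class TestSpearman:
    def test_monotone_invariance(self):
        x = [1.0, 2.5, 3.0, 7.0, 11.0]
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_antitone(self):
        x = [1, 2, 3, 4]
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [2, 1, 3, 4]
        assert spearman_rho(x, y) == pytest.approx(rank_definition_rho(x, y), abs=1e-12)

    def test_undefined_cases(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 2], [3, 4])
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([5, 5, 5], [1, 2, 3])

    def test_nan_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 3.0, 9.0, 5.0, 1.0]
        assert spearman_rho(x, y) == pytest.approx(
            rank_definition_rho([1, 2, 4, 5], [2, 3, 5, 1]), abs=1e-12
        )

    @settings(deadline=None, max_examples=300)
    @given(
        st.integers(3, 7).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 5), min_size=n, max_size=n),
                st.lists(st.integers(0, 5), min_size=n, max_size=n),
            )
        )
    )
    def test_matches_rank_definition_oracle(self, xy):
        x, y = xy
        try:
            got = spearman_rho(x, y)
        except UndefinedCorrelationError:
            assert np.ptp(x) == 0 or np.ptp(y) == 0
            return
        assert got == pytest.approx(rank_definition_rho(x, y), abs=1e-12)

    def test_symmetry(self):
        x, y = [3, 1, 4, 1, 5], [2, 7, 1, 8, 2]
        assert spearman_rho(x, y) == pytest.approx(spearman_rho(y, x))


def _score_table(per_case_per_set, method="M"):
    rows = []
    for case, by_set in per_case_per_set.items():
        for s, v in by_set.items():
            rows.append(
                {"case_id": case, "stain_set": s, "method": method, "psr_percent": v}
            )
    return pd.DataFrame(rows)


class TestMethodConsistency:
    def test_identical_scores_across_sets_give_rho_one(self):
        sets = ["E1", "E2", "N1", "N2"]
        values = {f"c{i}": {s: float(i) for s in sets} for i in range(1, 6)}
        scores = _score_table(values)
        pairs = build_stain_pairs(sets, DEFAULT_LABORATORY_OF)
        mc = method_consistency(scores, "M", pairs)
        assert len(mc.pairs) == 6
        assert all(p.rho == pytest.approx(1.0) for p in mc.pairs)
        assert mc.median_intra == mc.median_inter == pytest.approx(1.0)

    def test_constant_scores_reported_undefined_not_zero(self):
        sets = ["E1", "E2", "N1", "N2"]
        values = {f"c{i}": {s: 5.0 for s in sets} for i in range(5)}
        pairs = build_stain_pairs(sets, DEFAULT_LABORATORY_OF)
        mc = method_consistency(_score_table(values), "M", pairs)
        assert all(p.rho is None for p in mc.pairs)
        assert mc.median_intra is None

    def test_pair_rho_matches_oracle(self):
        rng = np.random.default_rng(4)
        sets = ["E1", "E2", "N1", "N2"]
        values = {
            f"c{i}": {s: float(rng.integers(0, 40)) for s in sets} for i in range(8)
        }
        scores = _score_table(values)
        pairs = build_stain_pairs(sets, DEFAULT_LABORATORY_OF)
        mc = method_consistency(scores, "M", pairs)
        wide = scores.pivot(index="case_id", columns="stain_set", values="psr_percent")
        for p in mc.pairs:
            expected = rank_definition_rho(wide[p.pair[0]], wide[p.pair[1]])
            assert p.rho == pytest.approx(expected, abs=1e-12)


class TestReferenceCorrelation:
    def test_self_correlation_is_one(self):
        scores = _score_table({f"c{i}": {"E1": float(i)} for i in range(5)})
        assert reference_correlation(scores, "M", "M", "E1") == pytest.approx(1.0)

    def test_reference_read_from_any_set(self):
        scores = pd.concat(
            [
                _score_table({f"c{i}": {"E1": float(i)} for i in range(5)}, "M"),
                _score_table({f"c{i}": {"SHG": float(10 - i)} for i in range(5)}, "REF"),
            ]
        )
        assert reference_correlation(scores, "M", "REF", "E1") == pytest.approx(-1.0)


class TestScoreTableIO:
    def test_round_trip(self, tmp_path):
        table = _score_table({"c1": {"E1": 10.0, "N1": 20.0}, "c2": {"E1": 5.0, "N1": 8.0}})
        path = tmp_path / "scores.csv"
        write_score_table(table, path)
        back = read_score_table(path)
        pd.testing.assert_frame_equal(
            back.sort_values(["case_id", "stain_set"]).reset_index(drop=True),
            table.sort_values(["case_id", "stain_set"]).reset_index(drop=True),
        )

    def test_cardinality_accepted(self, tmp_path):
        values = {f"c{i}": {s: 1.0 * i for s in ["E1", "E2", "N1", "N2"]} for i in range(20)}
        path = tmp_path / "t.csv"
        write_score_table(_score_table(values), path)
        assert len(read_score_table(path)) == 80

    def test_duplicate_rows_rejected(self, tmp_path):
        table = _score_table({"c1": {"E1": 10.0}})
        dup = pd.concat([table, table])
        path = tmp_path / "dup.csv"
        dup.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_score_table(path)

    def test_out_of_range_rejected(self, tmp_path):
        table = _score_table({"c1": {"E1": 120.0}})
        path = tmp_path / "bad.csv"
        table.to_csv(path, index=False)
        with pytest.raises(ValueError, match="psr_percent"):
            read_score_table(path)

    def test_xlsx_accepted(self, tmp_path):
        table = _score_table({"c1": {"E1": 10.0, "N1": 20.0}, "c2": {"E1": 1.0, "N1": 2.0}})
        path = tmp_path / "scores.xlsx"
        table.to_excel(path, index=False)
        back = read_score_table(path)
        assert len(back) == 4

    def test_report_files(self, tmp_path):
        sets = ["E1", "E2", "N1", "N2"]
        values = {f"c{i}": {s: float(i + len(s)) for s in sets} for i in range(5)}
        pairs = build_stain_pairs(sets, DEFAULT_LABORATORY_OF)
        report = ConsistencyReport()
        report.methods["M"] = method_consistency(_score_table(values), "M", pairs)
        pairs_path, summary_path = write_report(report, tmp_path)
        pair_df = pd.read_csv(pairs_path)
        summary_df = pd.read_csv(summary_path)
        assert len(pair_df) == 6
        # summaries recomputable from the emitted pair list
        med_intra = pair_df[pair_df["pair_type"] == "intra"]["rho"].median()
        assert summary_df["median_intra"].iloc[0] == pytest.approx(med_intra)
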