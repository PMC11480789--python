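"""Observed/expected prediction bias, citation correlation and stability."""

import numpy as np
import pytest

from priobench.bias import (
    AlignmentError,
    BiasRow,
    citation_correlation,
    expected_counts,
    never_predicted,
    odds_ratios,
    prediction_counts,
    stability_summary,
)
from priobench.cohort import Case
from priobench.metrics import OutcomeRecord
from priobench.parsing import ParsedPrediction, parse_response
from priobench import synthetic


def pred_of(*genes):
    return ParsedPrediction(
        genes=tuple(genes), fabricated=(), refusal=False, raw_text=", ".join(genes)
    )


class TestPredictionCounts:
    def test_counts_experiments_not_occurrences(self):
        preds = [pred_of("TP53", "BRCA1"), pred_of("TP53"), pred_of("BRCA1"), pred_of("PTEN")]
        counts = prediction_counts(preds, 10)
        assert counts == {"TP53": 2, "BRCA1": 2, "PTEN": 1}

    def test_never_emitted_gene_absent(self):
        assert prediction_counts([pred_of("TP53")], 10).get("EGFR", 0) == 0

    def test_duplicates_within_one_response_count_once(self, fixture_lexicon):
        pred = parse_response("TP53, TP53, BRCA1", fixture_lexicon)
        assert prediction_counts([pred], 10)["TP53"] == 1

    def test_truncation_at_k(self):
        pred = pred_of("TP53", "BRCA1", "PTEN")
        assert "PTEN" not in prediction_counts([pred], 2)


class TestExpectedCounts:
    def test_single_gene_pool_forced_value(self):
        assert expected_counts({"TP53": 7}, n_experiments=10, k=10) == {"TP53": 100.0}

    def test_pool_frequency_split(self):
        expected = expected_counts({"A1": 3, "B1": 1}, n_experiments=4, k=10)
        assert expected == {"A1": 30.0, "B1": 10.0}

    def test_pool_uniform_null(self):
        expected = expected_counts({"A1": 3, "B1": 1}, 4, 10, null_model="pool_uniform")
        assert expected == {"A1": 20.0, "B1": 20.0}

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            expected_counts({}, 10, 10)


class TestOddsRatios:
    def test_observed_equals_expected_gives_one(self):
        rows = odds_ratios({"TP53": 30}, {"TP53": 30.0}, {"TP53": 3})
        assert rows[0].odds_ratio == pytest.approx(1.0)

    def test_never_predicted_gives_zero(self):
        rows = odds_ratios({}, {"TP53": 30.0}, {"TP53": 3})
        assert rows[0].observed == 0 and rows[0].odds_ratio == 0.0

    def test_zero_expected_is_missing_not_infinite(self):
        rows = odds_ratios({"EGFR": 5}, {}, {})
        assert rows[0].odds_ratio is None

    def test_observed_sum_bounded_by_experiments_times_k(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}A" for i in range(30)]
        preds = [
            pred_of(*rng.choice(genes, size=5, replace=False)) for _ in range(40)
        ]
        counts = prediction_counts(preds, 5)
        assert sum(counts.values()) <= 40 * 5


class TestNeverPredicted:
    def test_always_hitting_responder_leaves_none(self):
        pool = {"A1": 1, "B1": 1}
        rows = odds_ratios({"A1": 4, "B1": 2}, expected_counts(pool, 6, 10), pool)
        assert never_predicted(rows, pool) == ([], 0)

    def test_silent_responder_misses_whole_pool(self):
        pool = {"A1": 1, "B1": 1, "C1": 1}
        rows = odds_ratios({}, expected_counts(pool, 6, 10), pool)
        genes, count = never_predicted(rows, pool)
        assert count == len(pool)

    def test_suppressed_subset_recovered_exactly(self, synthetic_world):
        # A responder whose filler weights exclude 20 chosen pool genes must
        # yield exactly those 20 as never-predicted.
        lexicon, _, _ = synthetic_world
        genes = sorted(lexicon.approved)[:40]
        pool = {g: 1 for g in genes}
        suppressed = set(genes[:20])
        weights = {g: 1.0 for g in genes if g not in suppressed}
        params = synthetic.ResponderParams(
            p_refuse=0.0, p_complete=1.0, p_hit=0.0, citation_weights=weights,
            p_fabricate=0.0, p_duplicate=0.0, p_comply=1.0,
        )
        rng = np.random.default_rng(5)
        case = Case("c", "s", (("HP:9000001", "x"),), "", genes[-1])
        preds = [
            parse_response(
                synthetic.simulate_response(case, params, 10, lexicon, rng), lexicon
            )
            for _ in range(200)
        ]
        rows = odds_ratios(
            prediction_counts(preds, 10), expected_counts(pool, 200, 10), pool
        )
        never, count = never_predicted(rows, pool)
        # the diagnosed gene is excluded from fillers, so it is also unseen
        assert set(never) == suppressed | {genes[-1]}


class TestCitationCorrelation:
    def test_monotone_construction_strongly_positive(self):
        rows = [
            BiasRow(f"G{i}A", observed=i, expected=10.0, odds_ratio=i / 10.0,
                    in_diagnosed_pool=True, pool_occurrences=1)
            for i in range(1, 31)
        ]
        citations = {f"G{i}A": 10 ** (1 + i / 10) for i in range(1, 31)}
        result = citation_correlation(rows, citations)
        assert result.coefficient > 0.9
        assert len(result.bin_summary) == 4
        means = result.bin_summary["mean_odds_ratio"].dropna().tolist()
        assert means == sorted(means)

    def test_permuted_citations_near_zero(self):
        rng = np.random.default_rng(11)
        ors = rng.random(100)
        rows = [
            BiasRow(f"G{i}A", observed=1, expected=1.0, odds_ratio=float(ors[i]),
                    in_diagnosed_pool=True, pool_occurrences=1)
            for i in range(100)
        ]
        citations = {f"G{i}A": float(10 ** rng.uniform(2, 6)) for i in range(100)}
        assert abs(citation_correlation(rows, citations).coefficient) < 0.3

    def test_two_genes_runs_with_low_n_flag(self):
        rows = [
            BiasRow("A1", 1, 1.0, 1.0, True, 1),
            BiasRow("B1", 2, 1.0, 2.0, True, 1),
        ]
        result = citation_correlation(rows, {"A1": 100, "B1": 1000})
        assert result.low_n

    def test_constant_or_vector_is_undefined(self):
        rows = [BiasRow(f"G{i}A", 1, 1.0, 1.0, True, 1) for i in range(5)]
        citations = {f"G{i}A": 10.0 ** (i + 1) for i in range(5)}
        result = citation_correlation(rows, citations)
        assert result.coefficient is None
        assert result.undefined_reason


class TestStability:
    @staticmethod
    def records(experiment, case, triplet, attr="complete"):
        out = []
        for t, value in enumerate(triplet, start=1):
            kwargs = {"complete": 0, "accurate": 0, "compliant": 0, attr: value}
            out.append(OutcomeRecord(experiment, case, t, **kwargs))
        return out

    def test_concordant_and_discordant_triplets(self):
        recs = self.records("e1", "c1", (1, 1, 1)) + self.records("e1", "c2", (1, 0, 1))
        summary = stability_summary(recs)
        assert summary.n_experiments == 2
        assert summary.n_discordant_completion == 1
        assert summary.n_discordant_accuracy == 0

    def test_single_iteration_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stability_summary(self.records("e1", "c1", (1,)))

    def test_cross_session_same_and_changed(self):
        first = self.records("e1", "c1", (1, 1, 1)) + self.records("e1", "c2", (1, 1, 0))
        second = self.records("e1", "c1", (1, 1, 1)) + self.records("e1", "c2", (0, 0, 0))
        summary = stability_summary(first, second)
        assert summary.cross_session["completion"] == {"same": 1, "changed": 1}

    def test_cross_session_mismatched_experiments_error(self):
        first = self.records("e1", "c1", (1, 1, 1))
        second = self.records("e1", "c2", (1, 1, 1))
        with pytest.raises(AlignmentError):
            stability_summary(first, second)
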