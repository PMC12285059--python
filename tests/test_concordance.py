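"""Five-way demultiplexing concordance and two-Gaussian multiplet calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from stealthmx import (
    MULTIPLET_TOKEN,
    UNASSIGNED_TOKEN,
    UNLABELLED_TOKEN,
    call_double_positives,
    classify_concordance,
    degrade_calls,
    equal_design,
    partial_stealth_candidates,
    simulate_pool,
    summarise_concordance,
    two_gaussian_threshold,
)
from stealthmx.datasets import CITESEQ_CONCORDANCE_COUNTS, NSCLC_CONCORDANCE_COUNTS


def oracle_concordance_class(ref_call: str, test_call: str, samples: set) -> str:
    """Row-by-row independent restatement of the five-way rule."""
    if test_call in samples and ref_call == test_call:
        return "singlet"
    if test_call in samples and ref_call == MULTIPLET_TOKEN:
        return "partial_stealth"
    if test_call == MULTIPLET_TOKEN and ref_call == MULTIPLET_TOKEN:
        return "multiplet"
    if test_call == UNASSIGNED_TOKEN:
        return "unassigned"
    return "discordant"


def table(pairs):
    return (
        pd.DataFrame({"barcode": [f"b{i}" for i in range(len(pairs))], "call": [p[0] for p in pairs]}),
        pd.DataFrame({"barcode": [f"b{i}" for i in range(len(pairs))], "call": [p[1] for p in pairs]}),
    )


class TestClassifyConcordance:
    def test_identical_sample_tables_are_all_singlets(self):
        pairs = [("A", "A")] * 5 + [("B", "B")] * 3
        ref, test = table(pairs)
        res = classify_concordance(ref, test)
        assert res.counts == {
            "singlet": 8, "partial_stealth": 0, "multiplet": 0,
            "unassigned": 0, "discordant": 0,
        }

    def test_reference_multiplet_called_singlet_is_partial_stealth(self):
        ref, test = table([(MULTIPLET_TOKEN, "A")])
        res = classify_concordance(ref, test, sample_vocabulary=["A", "B"])
        assert res.counts["partial_stealth"] == 1

    def test_all_call_pair_combinations_match_oracle(self):
        vocab = {"A", "B"}
        tokens = ["A", "B", MULTIPLET_TOKEN, UNLABELLED_TOKEN, UNASSIGNED_TOKEN]
        pairs = list(itertools.product(tokens, tokens))
        ref, test = table(pairs)
        res = classify_concordance(ref, test, sample_vocabulary=vocab)
        expected = {c: 0 for c in res.counts}
        for r, t in pairs:
            expected[oracle_concordance_class(r, t, vocab)] += 1
        assert res.counts == expected

    def test_random_tables_match_row_by_row_oracle(self, rng):
        vocab = {"A", "B", "C"}
        tokens = list(vocab) + [MULTIPLET_TOKEN, UNLABELLED_TOKEN, UNASSIGNED_TOKEN]
        n = 10_000
        ref_calls = rng.choice(tokens, size=n)
        test_calls = rng.choice(tokens, size=n)
        ref = pd.DataFrame({"barcode": [f"b{i}" for i in range(n)], "call": ref_calls})
        test = pd.DataFrame({"barcode": [f"b{i}" for i in range(n)], "call": test_calls})
        res = classify_concordance(ref, test, sample_vocabulary=vocab)
        expected = {c: 0 for c in res.counts}
        for r, t in zip(ref_calls, test_calls):
            expected[oracle_concordance_class(r, t, vocab)] += 1
        assert res.counts == expected

    def test_row_order_and_extra_barcodes_do_not_matter(self, rng):
        ref, test = table([("A", "A"), (MULTIPLET_TOKEN, "B"), ("B", UNASSIGNED_TOKEN)])
        extra = pd.DataFrame({"barcode": ["zz"], "call": ["A"]})
        ref_shuffled = pd.concat([ref.sample(frac=1, random_state=1), extra])
        res = classify_concordance(ref_shuffled, test, sample_vocabulary=["A", "B"])
        base = classify_concordance(ref, test, sample_vocabulary=["A", "B"])
        assert res.counts == base.counts
        assert res.n_ref_only == 1

    def test_empty_intersection_is_an_error(self):
        ref = pd.DataFrame({"barcode": ["x"], "call": ["A"]})
        test = pd.DataFrame({"barcode": ["y"], "call": ["A"]})
        with pytest.raises(ValueError, match="no barcodes"):
            classify_concordance(ref, test)

    def test_unknown_token_names_the_row(self):
        ref, test = table([("A", "A"), ("weird", "A")])
        with pytest.raises(ValueError, match="weird"):
            classify_concordance(ref, test, sample_vocabulary=["A"])


class TestSummariseConcordance:
    def test_nsclc_partial_stealth_burden(self):
        from stealthmx.concordance import ConcordanceResult

        res = ConcordanceResult(
            counts=dict(NSCLC_CONCORDANCE_COUNTS),
            n_common=sum(NSCLC_CONCORDANCE_COUNTS.values()),
        )
        report = summarise_concordance(res)
        burden = report["partial_stealth_among_monolabelled"]
        assert burden == pytest.approx(4285 / (24433 + 4285), rel=1e-12)
        assert round(burden * 100) == 15

    def test_citeseq_partial_stealth_burden(self):
        from stealthmx.concordance import ConcordanceResult

        res = ConcordanceResult(
            counts=dict(CITESEQ_CONCORDANCE_COUNTS),
            n_common=sum(CITESEQ_CONCORDANCE_COUNTS.values()),
        )
        report = summarise_concordance(res)
        assert report["partial_stealth_among_monolabelled"] == pytest.approx(
            624 / 14212, rel=1e-9
        )

    def test_all_singlet_gives_unit_ratio(self):
        from stealthmx.concordance import ConcordanceResult

        res = ConcordanceResult(
            counts={"singlet": 10, "partial_stealth": 0, "multiplet": 0,
                    "unassigned": 0, "discordant": 0},
            n_common=10,
        )
        assert summarise_concordance(res)["singlet_to_monolabelled_ratio"] == 1.0

    def test_no_monolabelled_droplets_flagged(self):
        from stealthmx.concordance import ConcordanceResult

        res = ConcordanceResult(
            counts={"singlet": 0, "partial_stealth": 0, "multiplet": 5,
                    "unassigned": 0, "discordant": 0},
            n_common=5,
        )
        assert summarise_concordance(res)["monolabelled_ratios_defined"] is False


class TestTwoGaussianThreshold:
    def test_well_separated_mixture(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        t = two_gaussian_threshold(scores, p=1e-4)
        assert 3.5 < t < 6.5
        high = scores[scores > 7]
        assert (high > t).all()

    def test_threshold_approaches_null_quantile(self, rng):
        mu, sigma = 2.0, 0.5
        scores = np.concatenate(
            [rng.normal(mu, sigma, 20000), rng.normal(mu + 10 * sigma, sigma, 5000)]
        )
        t = two_gaussian_threshold(scores, p=1e-4)
        expected = mu + norm.isf(1e-4) * sigma
        assert t == pytest.approx(expected, abs=0.15 * sigma)

    def test_by_adjustment_is_more_conservative(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        t_raw = two_gaussian_threshold(scores, p=1e-3)
        t_by = two_gaussian_threshold(scores, p=1e-3, adjust="BY")
        assert t_by >= t_raw

    def test_identical_scores_are_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_gaussian_threshold(np.ones(50))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            two_gaussian_threshold(np.arange(10))


class TestDoublePositives:
    @pytest.fixture
    def score_table(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "barcode": [f"b{i}" for i in range(n)],
                "lineage1": rng.normal(0, 1, n),
                "lineage2": rng.normal(0, 1, n),
            }
        )
        planted = ["b10", "b20", "b30", "b40", "b50"]
        df.loc[df["barcode"].isin(planted), ["lineage1", "lineage2"]] = 9.0
        return df, planted

    def test_nothing_above_thresholds(self, score_table):
        df, _ = score_table
        assert call_double_positives(df, {"lineage1": 99.0, "lineage2": 99.0}) == []

    def test_planted_double_positives_recovered(self, score_table):
        df, planted = score_table
        found = call_double_positives(df, {"lineage1": 5.0, "lineage2": 5.0})
        assert found == sorted(planted)

    def test_missing_scores_skip_rows(self, score_table):
        df, planted = score_table
        df.loc[df["barcode"] == planted[0], "lineage1"] = np.nan
        found = call_double_positives(df, {"lineage1": 5.0, "lineage2": 5.0})
        assert found == sorted(planted[1:])

    def test_monolabelled_double_positives_are_partial_stealth_candidates(self, score_table):
        df, planted = score_table
        calls = pd.DataFrame(
            {
                "barcode": df["barcode"],
                "call": ["A"] * len(df),
            }
        )
        # two of the planted multiplets were flagged by the demultiplexer
        calls.loc[calls["barcode"].isin(planted[:2]), "call"] = MULTIPLET_TOKEN
        dp = call_double_positives(df, {"lineage1": 5.0, "lineage2": 5.0})
        cands = partial_stealth_candidates(dp, calls, sample_vocabulary=["A"])
        assert cands == sorted(planted[2:])


class TestEndToEnd:
    def test_unassignment_rate_recovered_through_the_audit(self):
        p_un = 0.07
        pool = simulate_pool(equal_design(4, 0.9, 0.5), 30_000, seed=13, keep_droplets=True)
        truth, degraded = degrade_calls(pool, p_unassign=p_un, p_misassign=0.0, seed=14)
        res = classify_concordance(
            truth[["barcode", "call"]], degraded, sample_vocabulary=pool.design.names
        )
        frac = res.counts["unassigned"] / res.n_common
        se = math.sqrt(p_un * (1 - p_un) / res.n_common)
        assert abs(frac - p_un) <= 3 * se
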