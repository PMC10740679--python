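import itertools

import numpy as np
import pandas as pd
import pytest

from splicescape.containers import GeneSetCollection, SampleDesign, ValidationError
from splicescape.spea import (
    enrichment_score,
    gene_set_null,
    nes_p_fdr,
    snr_ranking,
    spea,
    spea_report,
)

DESIGN = SampleDesign.from_pairs(
    [(f"a{i}", "A") for i in range(2)] + [(f"b{i}", "B") for i in range(2)]
)


def das_from(rows):
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(DESIGN.samples), dtype=int
    )


def ranked_list(scores):
    return pd.Series(scores, index=[f"g{i + 1}" for i in range(len(scores))])


def exact_null(ranked, k, weight=1.0):
    """Independent oracle: ES of every one of the C(n, k) member sets."""
    return np.array(
        [
            enrichment_score(ranked, set(c), weight).es
            for c in itertools.combinations(ranked.index, k)
        ]
    )


class TestSnrRanking:
    def test_variance_floor_hand_example(self):
        # constant groups: sigma' = 0.2*|mu| -> (4-2)/(0.8+0.4)
        das = das_from({"g1": [4, 4, 2, 2]})
        score = snr_ranking(das, DESIGN, "A", "B")["g1"]
        assert score == pytest.approx(2 / 1.2)

    def test_identical_groups_score_zero(self):
        das = das_from({"g1": [3, 3, 3, 3]})
        assert snr_ranking(das, DESIGN, "A", "B")["g1"] == 0.0

    def test_pair_swap_negates_scores(self):
        rng = np.random.default_rng(12)
        das = pd.DataFrame(
            rng.integers(0, 7, (100, 4)),
            index=[f"G{i:03d}" for i in range(100)],
            columns=list(DESIGN.samples),
        )
        fwd = snr_ranking(das, DESIGN, "A", "B")
        rev = snr_ranking(das, DESIGN, "B", "A")
        assert np.allclose(fwd.sort_index(), -rev.sort_index())

    def test_descending_order_with_lexicographic_ties(self):
        das = das_from({"z": [3, 3, 1, 1], "a": [3, 3, 1, 1], "m": [9, 9, 1, 1]})
        ranked = snr_ranking(das, DESIGN, "A", "B")
        assert list(ranked.index) == ["m", "a", "z"]

    def test_single_sample_group_needs_diff_metric(self):
        design = SampleDesign.from_pairs([("a1", "A"), ("b1", "B"), ("b2", "B")])
        das = pd.DataFrame({"a1": [4], "b1": [2], "b2": [2]}, index=["g1"])
        with pytest.raises(ValidationError, match="diff"):
            snr_ranking(das, design, "A", "B")
        assert snr_ranking(das, design, "A", "B", metric="diff")["g1"] == 2.0

    def test_gene_filter_restricts_universe(self):
        das = das_from({"g1": [4, 4, 2, 2], "g2": [1, 1, 1, 1]})
        ranked = snr_ranking(das, DESIGN, "A", "B", gene_filter={"g1"})
        assert list(ranked.index) == ["g1"]


class TestEnrichmentScore:
    def test_hand_walked_running_sum(self):
        ranked = ranked_list([2.0, 1.0, 0.5, -1.0, -2.0])
        result = enrichment_score(ranked, {"g1", "g3"}, weight=1.0)
        expected = [0.8, 0.8 - 1 / 3, 0.8 - 1 / 3 + 0.2, 0.8 - 1 / 3 + 0.2 - 1 / 3, 0.0]
        assert result.running_sum == pytest.approx(expected)
        assert result.es == pytest.approx(0.8)
        assert result.peak_index == 0

    def test_all_genes_member_es_one_at_last_rank(self):
        ranked = ranked_list([2.0, 1.0, 0.5])
        result = enrichment_score(ranked, {"g1", "g2", "g3"})
        assert result.es == pytest.approx(1.0)
        assert result.peak_index == len(ranked) - 1

    def test_bottom_only_member_gives_negative_es(self):
        ranked = ranked_list([2.0, 1.0, 0.5, -1.0, -2.0])
        assert enrichment_score(ranked, {"g5"}).es < 0

    def test_no_member_present_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_score(ranked_list([1.0, 0.5]), {"absent"})

    def test_es_bounded_on_randomized_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(3, 30)
            ranked = ranked_list(np.sort(rng.normal(0, 2, n))[::-1])
            k = int(rng.integers(1, n + 1))
            members = set(rng.choice(ranked.index, k, replace=False))
            assert -1.0 <= enrichment_score(ranked, members).es <= 1.0


class TestGeneSetNull:
    def test_sample_size(self):
        null = gene_set_null(ranked_list([3.0, 2.0, 1.0, -1.0]), 2, n_perm=1000, seed=5)
        assert null.shape == (1000,)

    def test_batch_agrees_with_plain_running_sum(self):
        # independent oracle: a literal step-by-step walk of the running sum
        def walk_extremes(scores, member_idx):
            w = np.abs(scores)
            total = w[sorted(member_idx)].sum()
            value, pos, neg = 0.0, -np.inf, np.inf
            d = 1.0 / (len(scores) - len(member_idx))
            for i, s in enumerate(scores):
                value += w[i] / total if i in member_idx else -d
                pos, neg = max(pos, value), min(neg, value)
            return pos, neg

        rng = np.random.default_rng(9)
        ranked = ranked_list(np.sort(rng.normal(0, 1, 12))[::-1])
        for _ in range(100):
            k = int(rng.integers(1, 6))
            idx = set(map(int, rng.choice(12, k, replace=False)))
            fast = enrichment_score(ranked, {ranked.index[i] for i in idx}).es
            pos, neg = walk_extremes(ranked.to_numpy(), idx)
            if pos > -neg + 1e-9:
                assert fast == pytest.approx(pos)
            elif pos < -neg - 1e-9:
                assert fast == pytest.approx(neg)
            else:  # exact tie: either signed extreme is acceptable
                assert abs(fast) == pytest.approx(pos)

    def test_seeded_mean_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        ranked = ranked_list(np.sort(rng.normal(0, 1, 6))[::-1])
        exact = exact_null(ranked, 2)  # all C(6,2) = 15 subsets
        assert exact.shape == (15,)
        null = gene_set_null(ranked, 2, n_perm=4000, seed=8)
        se = exact.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean() - exact.mean()) < 3 * se

    def test_near_saturated_sets_score_lower_than_singletons(self):
        rng = np.random.default_rng(0)
        ranked = ranked_list(np.sort(rng.normal(0, 1, 6))[::-1])
        wide = gene_set_null(ranked, 5, n_perm=2000, seed=1)
        narrow = gene_set_null(ranked, 1, n_perm=2000, seed=1)
        assert np.abs(wide).mean() < np.abs(narrow).mean()

    def test_determinism(self):
        ranked = ranked_list([3.0, 1.0, -2.0, -4.0])
        a = gene_set_null(ranked, 2, 100, seed=7)
        b = gene_set_null(ranked, 2, 100, seed=7)
        assert (a == b).all()


class TestNesPFdr:
    def test_nes_one_when_es_equals_mean_positive_null(self):
        nulls = {"S": np.array([0.2, 0.4, 0.6, -0.3])}
        records = nes_p_fdr({"S": 0.4}, nulls)
        assert records.loc["S", "nes"] == pytest.approx(1.0)

    def test_add_one_correction_bound(self):
        nulls = {"S": np.array([0.1] * 99)}
        records = nes_p_fdr({"S": 0.9}, nulls)
        assert records.loc["S", "p_nominal"] == pytest.approx(1 / 100)

    def test_no_same_sign_null_flags_nan(self):
        nulls = {"S": np.array([0.1, 0.2])}
        records = nes_p_fdr({"S": -0.5}, nulls)
        assert np.isnan(records.loc["S", "nes"])
        assert not records.loc["S", "significant"]

    def test_direction_follows_es_sign(self):
        nulls = {"P": np.array([0.1, -0.1]), "N": np.array([0.1, -0.1])}
        records = nes_p_fdr({"P": 0.5, "N": -0.5}, nulls)
        assert records.loc["P", "direction"] == "positive"
        assert records.loc["N", "direction"] == "negative"

    def test_permutation_p_converges_to_exact_subset_tail(self):
        # 8-gene list, size-3 sets: enumeration of all C(8,3) subsets is the
        # independent oracle for the same-sign tail probability
        rng = np.random.default_rng(6)
        ranked = ranked_list(np.sort(rng.normal(0, 1.5, 8))[::-1])
        members = {"g1", "g4", "g6"}
        es = enrichment_score(ranked, members).es
        exact = exact_null(ranked, 3)
        same_sign = exact[exact >= 0] if es >= 0 else exact[exact < 0]
        q_exact = (np.abs(same_sign) >= abs(es)).mean()

        null = gene_set_null(ranked, 3, n_perm=10000, seed=2)
        sampled = null[null >= 0] if es >= 0 else null[null < 0]
        q_perm = (np.abs(sampled) >= abs(es)).mean()
        se = np.sqrt(max(q_exact * (1 - q_exact), 1e-12) / sampled.size)
        assert abs(q_perm - q_exact) < 3 * se + 1e-9


class TestSpeaEndToEnd:
    def test_planted_top_set_significant_and_oracle_checked(self):
        # strong genes planted at the top of the list must clear the
        # |NES| > 1.5, p < 0.05, q < 0.25 filter; the exhaustive size-3 null
        # (all C(40,3) subsets) independently confirms the tail probability.
        # Small member sets on short lists have an intrinsically fat null ES
        # (the known small-set pathology of gene-set permutation), so the
        # planted set uses 4 members on a 60-gene list.
        scores = np.concatenate([np.linspace(6.0, 5.0, 3), np.linspace(1.0, -1.0, 37)])
        ranked = ranked_list(scores)
        es = enrichment_score(ranked, {"g1", "g2", "g3"}).es
        exact = exact_null(ranked, 3)
        exact_p = (np.abs(exact[exact >= 0]) >= es).mean()
        assert exact_p < 0.05

        scores60 = np.concatenate([np.linspace(6.0, 5.0, 4), np.linspace(1.0, -1.0, 56)])
        das = das_from(
            {
                f"g{i + 1}": [4 + round(2 * s), 4 + round(2 * s), 4, 4]
                for i, s in enumerate(scores60)
            }
        )
        collection = GeneSetCollection({"TOP": frozenset({"g1", "g2", "g3", "g4"})})
        records = spea(das, DESIGN, "A", "B", collection, n_perm=1000, seed=3)
        row = records.loc["TOP"]
        assert row["nes"] > 1.5 and row["p_nominal"] < 0.05 and row["fdr_q"] < 0.25
        assert bool(row["significant"])

    def test_type_one_error_calibrated_on_null_sets(self):
        # without planted signal the nominal p of random sets is uniform:
        # the fraction below 0.05 stays within 3 binomial SE of 0.05
        rng = np.random.default_rng(42)
        genes = [f"G{i:03d}" for i in range(300)]
        das = pd.DataFrame(
            rng.integers(0, 7, (300, 4)), index=genes, columns=list(DESIGN.samples)
        )
        sets = {
            f"R{j}": frozenset(rng.choice(genes, 10, replace=False)) for j in range(200)
        }
        records = spea(
            das, DESIGN, "A", "B", GeneSetCollection(sets), n_perm=500, seed=11
        )
        frac = (records["p_nominal"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(frac - 0.05) < 3 * se

    def test_pair_swap_flips_every_sign(self):
        rng = np.random.default_rng(12)
        genes = [f"G{i:03d}" for i in range(100)]
        das = pd.DataFrame(
            rng.integers(0, 7, (100, 4)), index=genes, columns=list(DESIGN.samples)
        )
        # restrict to genes with unique scores so both orders are exact mirrors
        fwd_scores = snr_ranking(das, DESIGN, "A", "B")
        unique = fwd_scores.drop_duplicates(keep=False).index
        sets = {
            f"R{j}": frozenset(rng.choice(unique, 8, replace=False)) for j in range(10)
        }
        collection = GeneSetCollection(sets)
        fwd = spea(das, DESIGN, "A", "B", collection, gene_filter=set(unique), n_perm=200, seed=5)
        rev = spea(das, DESIGN, "B", "A", collection, gene_filter=set(unique), n_perm=200, seed=5)
        assert np.allclose(fwd["es"], -rev["es"])
        assert (np.sign(fwd["nes"]) == -np.sign(rev["nes"])).all()


class TestSpeaReport:
    def test_threshold_filtering(self):
        nulls = {
            "weak": np.array([0.5, 0.7, -0.5]),
            "strong": np.array([0.3, 0.5, -0.5]),
        }
        records = nes_p_fdr({"weak": 0.8, "strong": 0.9}, nulls)
        # weak: nes = 0.8/0.6 = 1.33 < 1.5 -> never significant
        assert records.loc["weak", "nes"] < 1.5
        assert not records.loc["weak", "significant"]

    def test_sorted_by_nes_with_pair_label(self):
        nulls = {"a": np.array([0.4, -0.4]), "b": np.array([0.4, -0.4])}
        records = nes_p_fdr({"a": 0.2, "b": 0.8}, nulls)
        report = spea_report(records, "A_vs_B")
        assert list(report.index) == ["b", "a"]
        assert (report["pair"] == "A_vs_B").all()

    def test_empty_records(self):
        report = spea_report(pd.DataFrame(), "A_vs_B")
        assert report.empty
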