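"""Per-cohort one-sided tests and median-rank meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tfscreen.rna_screen import (
    ExpressionCohort,
    cohort_pvalues,
    de_pvalue_one_sided,
    median_rank_aggregate,
    rank_by_significance,
    select_candidates,
)
from tfscreen.simulate import SimConfig, gen_expression_cohorts


def make_cohort(case_rows, control_rows, genes=None, cohort_id="c1"):
    case = np.atleast_2d(np.asarray(case_rows, dtype=float))
    control = np.atleast_2d(np.asarray(control_rows, dtype=float))
    genes = genes or [f"g{i}" for i in range(case.shape[0])]
    values = np.hstack([case, control])
    samples = [f"s{i}" for i in range(values.shape[1])]
    group = pd.Series([1] * case.shape[1] + [0] * control.shape[1], index=samples)
    return ExpressionCohort(cohort_id, pd.DataFrame(values, index=genes, columns=samples), group)


class TestDePvalue:
    def test_welch_hand_oracle(self):
        # case {2,3,4} vs control {0,1,2}: t = 2 / sqrt(1/3 + 1/3) = sqrt(6),
        # Welch df = (2/3)^2 / (2 * (1/3)^2 / 2) = 4
        cohort = make_cohort([[2, 3, 4]], [[0, 1, 2]])
        expected = float(stats.t.sf(np.sqrt(6.0), 4.0))
        assert de_pvalue_one_sided(cohort, "g0") == pytest.approx(expected, rel=1e-12)
        assert de_pvalue_one_sided(cohort, "g0") == pytest.approx(0.035242, abs=5e-6)

    def test_label_swap_maps_p_to_one_minus_p(self, rng):
        case = rng.normal(1, 1, size=8)
        control = rng.normal(0, 1, size=6)
        p = de_pvalue_one_sided(make_cohort([case], [control]), "g0")
        p_swapped = de_pvalue_one_sided(make_cohort([control], [case]), "g0")
        assert p + p_swapped == pytest.approx(1.0)

    def test_identical_groups_give_half_by_convention(self):
        cohort = make_cohort([[3, 3, 3]], [[3, 3, 3]])
        with pytest.warns(UserWarning, match="zero variance"):
            assert de_pvalue_one_sided(cohort, "g0") == 0.5

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError):
            de_pvalue_one_sided(make_cohort([[1, 2]], [[0, 1]]), "nope")

    def test_vectorised_path_matches_scalar_scipy(self, rng):
        case = rng.normal(0.5, 1.2, size=(30, 7))
        control = rng.normal(0, 0.8, size=(30, 9))
        cohort = make_cohort(case, control)
        vec = cohort_pvalues(cohort)
        for gene in ["g0", "g7", "g29"]:
            i = int(gene[1:])
            ref = stats.ttest_ind(
                case[i], control[i], equal_var=False, alternative="greater"
            ).pvalue
            assert vec[gene] == pytest.approx(ref, rel=1e-10)


class TestRanks:
    def test_simple_and_tied_ranks(self):
        p = pd.Series({"a": 0.01, "b": 0.5, "c": 0.9})
        assert rank_by_significance(p).to_dict() == {"a": 1, "b": 2, "c": 3}
        tied = rank_by_significance(pd.Series({"a": 0.2, "b": 0.2, "c": 0.9}))
        assert tied["a"] == tied["b"] == 1.5

    @given(st.lists(st.floats(0.001, 1.0), min_size=2, max_size=12, unique=True))
    def test_order_invariance(self, ps):
        genes = [f"g{i}" for i in range(len(ps))]
        s = pd.Series(ps, index=genes)
        shuffled = s.sample(frac=1, random_state=3)
        assert rank_by_significance(s).sort_index().equals(
            rank_by_significance(shuffled).sort_index()
        )


def brute_force_median_rank(p_by_cohort, min_fraction=0.5):
    """Test-local oracle: explicit sort / median / lookup per gene."""
    from scipy.stats import rankdata

    ranks = {
        cid: dict(zip(p.index, rankdata(p.to_numpy())))
        for cid, p in p_by_cohort.items()
    }
    genes = sorted(set(g for p in p_by_cohort.values() for g in p.index))
    out = {}
    for g in genes:
        triples = sorted(
            (ranks[cid][g], float(p[g]), cid)
            for cid, p in p_by_cohort.items()
            if g in p.index
        )
        if len(triples) / len(p_by_cohort) < min_fraction:
            continue
        med = triples[len(triples) // 2]
        out[g] = (med[0], med[1])
    return out


class TestMedianRankAggregate:
    def test_single_cohort_is_identity(self):
        p = pd.Series({"a": 0.01, "b": 0.3})
        meta = median_rank_aggregate({"c1": p})
        assert meta.loc["a", "median_rank"] == 1
        assert meta.loc["a", "median_rank_p"] == 0.01
        assert meta.loc["b", "median_rank_p"] == 0.3

    def test_odd_count_definition(self):
        # gene 'x' sits at rank 3, 7 and 9 in three 9-gene cohorts with
        # p-values 0.001, 0.03 and 0.2 at those ranks
        cohorts = {}
        for cid, (rank, px) in zip("abc", [(3, 0.001), (7, 0.03), (9, 0.2)]):
            ps = {}
            others = iter(f"f{cid}{j}" for j in range(8))
            for pos in range(1, 10):
                gene = "x" if pos == rank else next(others)
                base = px if pos == rank else (pos / 10) * px if pos < rank else pos / 10 + px
                ps[gene] = base
            s = pd.Series(ps)
            assert float(s.rank()[["x"]].iloc[0]) == rank
            cohorts[cid] = s
        meta = median_rank_aggregate(cohorts, min_fraction_measured=0.0)
        assert meta.loc["x", "median_rank"] == 7
        assert meta.loc["x", "median_rank_p"] == 0.03
        assert meta.loc["x", "median_rank_cohort"] == "b"

    def test_even_count_takes_less_significant_middle(self):
        cohorts = {
            "a": pd.Series({"x": 0.01, "y": 0.5, "z": 0.9}),
            "b": pd.Series({"x": 0.6, "y": 0.2, "z": 0.8}),
        }
        meta = median_rank_aggregate(cohorts)
        # x ranks 1 and 2 -> upper middle is rank 2 with p=0.6 from cohort b
        assert meta.loc["x", "median_rank"] == 2
        assert meta.loc["x", "median_rank_p"] == 0.6

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(20):
            n_cohorts = int(rng.integers(1, 8))
            n_genes = int(rng.integers(3, 60))
            genes = [f"g{i}" for i in range(n_genes)]
            table = {}
            for c in range(n_cohorts):
                keep = rng.random(n_genes) > 0.2
                if not keep.any():
                    keep[0] = True
                table[f"c{c}"] = pd.Series(
                    rng.random(int(keep.sum())),
                    index=[g for g, k in zip(genes, keep) if k],
                )
            meta = median_rank_aggregate(table, min_fraction_measured=0.5)
            oracle = brute_force_median_rank(table, 0.5)
            assert set(meta.index) == set(oracle)
            for g in oracle:
                assert meta.loc[g, "median_rank"] == pytest.approx(oracle[g][0])
                assert meta.loc[g, "median_rank_p"] == pytest.approx(oracle[g][1])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            median_rank_aggregate({})


class TestSelectCandidates:
    def test_alpha_extremes(self):
        meta = pd.DataFrame(
            {"median_rank": [1.0, 2.0], "median_rank_p": [0.01, 0.2]},
            index=["a", "b"],
        )
        assert select_candidates(meta, ["a", "b"], alpha=0.0) == []
        assert select_candidates(meta, ["a", "b"], alpha=1.0) == ["a", "b"]
        with pytest.raises(ValueError):
            select_candidates(meta, [], alpha=0.05)

    def test_planted_recovery_and_false_positives(self):
        cfg = SimConfig(
            seed=4, n_cohorts=5, n_genes=300, n_tf_genes=100,
            n_samples_per_group=30, effect_size=2.0, n_planted_de=20,
        )
        cohorts, truth = gen_expression_cohorts(cfg)
        p_by_cohort = {c.cohort_id: cohort_pvalues(c) for c in cohorts}
        meta = median_rank_aggregate(p_by_cohort)
        tfs = [f"TF{i:04d}" for i in range(1, 101)]
        selected = set(select_candidates(meta, tfs, alpha=0.05))
        planted = set(truth.de_tfs)
        recall = len(selected & planted) / len(planted)
        fpr = len(selected - planted) / (len(tfs) - len(planted))
        assert recall >= 0.95
        assert fpr <= 0.07

    def test_per_cohort_power_at_planted_effect(self):
        # one-sided Welch at effect 2.0, n=30/group has power ~1 - Phi-ish;
        # computed from the noncentral t: >0.99, so demand >=0.95 rejection
        cfg = SimConfig(
            seed=9, n_cohorts=5, n_genes=200, n_tf_genes=60,
            n_samples_per_group=30, effect_size=2.0, n_planted_de=20,
        )
        nc = 2.0 * np.sqrt(30 / 2)
        tcrit = stats.t.ppf(0.95, 58)
        power = 1 - stats.nct.cdf(tcrit, 58, nc)
        assert power > 0.99
        cohorts, truth = gen_expression_cohorts(cfg)
        rejections = []
        for c in cohorts:
            p = cohort_pvalues(c)
            rejections.extend(p[truth.de_tfs] < 0.05)
        assert np.mean(rejections) >= 0.95
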