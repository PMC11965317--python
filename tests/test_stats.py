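"""Correlation, FDR, coexpression, permutation and enrichment statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from efpa.stats import (
    celltype_enrichment,
    cross_informing_rate,
    delta_rfp,
    enrichment_flags,
    pathway_coexpression,
    pearson_fdr,
    permutation_pvalue,
    permute_labels,
)


def bh_stepup(pvals):
    """Independent BH oracle: classic step-up with monotonicity repair."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


class TestPearsonFdr:
    def test_perfect_linearity(self):
        x = pd.DataFrame([np.arange(10.0)], index=["R"])
        y = 2 * x + 1
        out = pearson_fdr(x, y)
        assert out.loc["R", "pcc"] == pytest.approx(1.0)
        assert out.loc["R", "significant"]

    def test_bh_stepup_example(self):
        rng = np.random.default_rng(0)
        n = 12
        x = pd.DataFrame(rng.normal(size=(3, n)), index=list("abc"))
        y = pd.DataFrame(
            [x.iloc[0] + rng.normal(0, 0.1, n),
             x.iloc[1] + rng.normal(0, 0.5, n),
             rng.normal(size=n)],
            index=list("abc"),
        )
        out = pearson_fdr(x, y)
        assert np.allclose(
            out["q"], bh_stepup(out["p"].to_numpy()), atol=1e-12
        )

    def test_bh_matches_oracle_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.allclose(
                multipletests(p, method="fdr_bh")[1], bh_stepup(p), atol=1e-12
            )

    def test_constant_row_excluded_from_family(self):
        x = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]], index=["flat", "ok"]
        )
        y = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.1, 2.2, 2.9, 4.1]], index=["flat", "ok"]
        )
        out = pearson_fdr(x, y)
        assert not out.loc["flat", "tested"]
        assert np.isnan(out.loc["flat", "q"])
        # FDR family is the single tested row
        assert out.loc["ok", "q"] == pytest.approx(out.loc["ok", "p"])

    def test_short_rows_excluded(self):
        x = pd.DataFrame([[1.0, 2.0, np.nan, np.nan]], index=["R"])
        y = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["R"])
        assert not pearson_fdr(x, y).loc["R", "tested"]


class TestPathwayCoexpression:
    def test_identical_rows_strength_one(self):
        rel = pd.DataFrame([[0.1, 0.5, 1.0]] * 2, index=["a", "b"])
        s, profile = pathway_coexpression(rel, ["a", "b"])
        assert s == pytest.approx(1.0)
        assert np.allclose(profile, rel.iloc[0])

    def test_anticorrelated_pair(self):
        rel = pd.DataFrame([[0.0, 0.5, 1.0], [1.0, 0.5, 0.0]],
                           index=["a", "b"])
        s, _ = pathway_coexpression(rel, ["a", "b"])
        assert s == pytest.approx(-1.0)

    def test_four_members_match_six_pair_oracle(self):
        rng = np.random.default_rng(2)
        rel = pd.DataFrame(rng.uniform(size=(4, 25)), index=list("abcd"))
        s, profile = pathway_coexpression(rel, list("abcd"))
        pccs = [
            sps.pearsonr(rel.loc[i], rel.loc[j])[0]
            for i, j in itertools.combinations("abcd", 2)
        ]
        assert len(pccs) == 6
        assert s == pytest.approx(np.median(pccs))
        assert np.allclose(profile, rel.median(axis=0))

    def test_single_member_undefined(self):
        rel = pd.DataFrame([[0.1, 0.5]], index=["a"])
        s, _ = pathway_coexpression(rel, ["a"])
        assert np.isnan(s)


class TestCrossInformingRate:
    def test_proportions(self):
        pairs = pd.DataFrame(
            {"degree": [2, 2, 2, 2], "pcc": [0.9, 0.5, -0.2, 0.1],
             "q": [0.01, 0.2, 0.01, 0.5]}
        )
        out = cross_informing_rate(pairs, n_bins=1)
        assert out.loc[0, "rate"] == pytest.approx(0.25)

    def test_all_significant(self):
        pairs = pd.DataFrame(
            {"degree": [2, 4], "pcc": [0.9, 0.8], "q": [0.01, 0.01]}
        )
        out = cross_informing_rate(pairs, n_bins=1)
        assert out.loc[0, "rate"] == 1.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        pairs = pd.DataFrame(
            {"degree": rng.integers(2, 40, 200).astype(float),
             "pcc": rng.uniform(-1, 1, 200),
             "q": rng.uniform(0, 0.2, 200)}
        )
        out = cross_informing_rate(pairs, n_bins=4)
        assert out["n_pairs"].sum() == 200
        total_rate = (out["rate"] * out["n_pairs"]).sum() / 200
        expected = ((pairs["q"] <= 0.05) & (pairs["pcc"] > 0)).mean()
        assert total_rate == pytest.approx(expected)


class TestPermutation:
    def test_identity_statistic_reproduced(self):
        rel = pd.DataFrame(np.arange(6.0).reshape(3, 2),
                           index=["a", "b", "c"])
        p, obs, null = permutation_pvalue(
            lambda df: df.loc["a"].sum() if "a" in df.index else 0.0,
            rel, n_perm=10, seed=0,
        )
        assert obs == rel.loc["a"].sum()

    def test_two_row_matrix_has_two_permutations(self):
        rel = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"])
        rng = np.random.default_rng(0)
        seen = {tuple(permute_labels(rel, rng).index) for _ in range(50)}
        assert seen == {("a", "b"), ("b", "a")}

    def test_values_stay_with_rows(self):
        rel = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"])
        perm = permute_labels(rel, np.random.default_rng(1))
        assert sorted(map(tuple, perm.to_numpy().tolist())) == \
            [(1.0, 2.0), (3.0, 4.0)]

    def test_p_never_zero(self):
        rel = pd.DataFrame(np.eye(3), index=list("abc"))
        p, _, _ = permutation_pvalue(lambda df: 1e9, rel, n_perm=5, seed=0)
        assert p > 0

    def test_null_calibration_uniform(self):
        """Under a null matched-pair statistic the empirical p is
        ~Uniform(0,1): the fraction below 0.25 stays within binomial error
        of 0.25.  The statistic spans the full label assignment (each row
        scored against its own target), mirroring the real use where every
        reaction is correlated with its matched flux row."""
        rng = np.random.default_rng(4)
        targets = pd.DataFrame(rng.normal(size=(6, 8)),
                               index=[f"r{j}" for j in range(6)])

        def stat(df):
            return float(sum(
                np.corrcoef(df.loc[r], targets.loc[r])[0, 1]
                for r in df.index
            ))

        ps = []
        for i in range(120):
            rel = pd.DataFrame(
                rng.normal(size=(6, 8)), index=[f"r{j}" for j in range(6)]
            )
            p, _, _ = permutation_pvalue(stat, rel, n_perm=200, seed=1000 + i)
            ps.append(p)
        frac = np.mean(np.array(ps) <= 0.25)
        se = np.sqrt(0.25 * 0.75 / len(ps))
        assert abs(frac - 0.25) < 4 * se + 1 / 201


class TestDeltaRfp:
    def test_centering(self):
        rfp = pd.DataFrame([[0.1, 0.5, 0.9]], index=["R"],
                           columns=["t1", "t2", "t3"])
        d = delta_rfp(rfp)
        assert list(d.loc["R"]) == pytest.approx([-0.4, 0.0, 0.4])

    def test_constant_row_all_zero(self):
        rfp = pd.DataFrame([[0.3, 0.3, 0.3]], index=["R"])
        assert (delta_rfp(rfp) == 0).all().all()

    def test_undefined_excluded_from_median(self):
        rfp = pd.DataFrame([[0.2, np.nan, 0.8]], index=["R"])
        d = delta_rfp(rfp)
        assert d.iloc[0, 0] == pytest.approx(-0.3)

    def test_enrichment_thresholds(self):
        rfp = pd.DataFrame([[0.1, 0.5, 0.9]], index=["R"],
                           columns=["t1", "t2", "t3"])
        flags = enrichment_flags(delta_rfp(rfp), threshold=0.2)
        assert flags.loc["R", "t1"] == "depleted"
        assert flags.loc["R", "t2"] == ""
        assert flags.loc["R", "t3"] == "enriched"


class TestCellTypeEnrichment:
    def _data(self, shift=0.0, n=100, seed=0):
        rng = np.random.default_rng(seed)
        cells, labels, vals = [], [], []
        for t in ("alpha", "beta", "gamma"):
            for i in range(n):
                cells.append(f"{t}{i}")
                labels.append(t)
                vals.append(rng.normal(shift if t == "alpha" else 0.0, 1.0) + 5)
        return (pd.Series(vals, index=cells),
                pd.Series(labels, index=cells))

    def test_identical_distributions_not_enriched(self):
        scores, labels = self._data(shift=0.0)
        out = celltype_enrichment(scores, labels)
        assert not out["enriched"].any()
        assert np.allclose(out["fc"], 1.0, atol=0.15)

    def test_shifted_type_flagged(self):
        scores, labels = self._data(shift=1.5)
        out = celltype_enrichment(scores, labels)
        assert out.loc["alpha", "enriched"]
        assert out.loc["alpha", "rank"] == 1

    def test_top_rank_excludes_second(self):
        scores, labels = self._data(shift=1.5)
        out = celltype_enrichment(scores, labels)
        # the tested top type must not be compared against the runner-up
        assert out.loc["alpha", "excluded"] != "alpha"
        runner_up = out.sort_values("rank").index[1]
        assert out.loc["alpha", "excluded"] == runner_up
        # non-top types exclude the top type
        assert out.loc["gamma", "excluded"] == "alpha"

    def test_normal_approx_close_to_exact_enumeration(self):
        """Tie-free small samples: the tie-corrected normal approximation
        tracks the exact rank-sum null within 10%."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n1, n2 = rng.integers(4, 11, 2)
            x = rng.normal(size=n1)
            y = rng.normal(0.5, 1.0, size=n2)
            exact = sps.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
            approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
            assert approx == pytest.approx(exact, rel=0.10, abs=0.02)
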