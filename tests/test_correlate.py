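import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathseer.core_data import ExpressionMatrix, FeatureTable, ValidationError
from pathseer.correlate import (
    correlate_pairs,
    decay_weights,
    mad,
    mad_rescale,
    mutual_rank,
)


class TestMad:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4, 100], 1.0),
            ([5, 5, 5], 0.0),
            ([-1, 1], 1.0),
        ],
    )
    def test_hand_computed_values(self, values, expected):
        assert mad(values) == pytest.approx(expected)

    def test_empty_vector_errors(self):
        with pytest.raises(ValidationError):
            mad([])


class TestMadRescale:
    def test_hand_computed_row(self):
        em = ExpressionMatrix(
            pd.DataFrame([[1, 2, 3, 4, 100]], index=["t"], columns=list("abcde"))
        )
        out = mad_rescale(em)
        assert out.values.loc["t"].tolist() == [-2, -1, 0, 1, 97]

    def test_constant_rows_dropped(self):
        em = ExpressionMatrix(
            pd.DataFrame([[5, 5, 5], [1, 2, 3]], index=["flat", "ok"], columns=list("abc"))
        )
        out = mad_rescale(em)
        assert out.transcript_ids == ["ok"]

    def test_all_constant_errors(self):
        em = ExpressionMatrix(pd.DataFrame([[5, 5, 5]], index=["flat"], columns=list("abc")))
        with pytest.raises(ValidationError, match="no variable rows"):
            mad_rescale(em)

    def test_rescaled_rows_have_median_zero_mad_one(self):
        rng = np.random.default_rng(0)
        em = ExpressionMatrix(
            pd.DataFrame(rng.gamma(2.0, 3.0, (10, 9)), index=[f"t{i}" for i in range(10)],
                         columns=[f"s{j}" for j in range(9)])
        )
        out = mad_rescale(em).values.to_numpy()
        assert np.allclose(np.median(out, axis=1), 0.0)
        assert np.allclose(np.median(np.abs(out), axis=1), 1.0)


def _paired(x_rows, y_rows, samples):
    em = ExpressionMatrix(
        pd.DataFrame(x_rows, index=[f"t{i}" for i in range(len(x_rows))], columns=samples)
    )
    ft = FeatureTable(
        pd.Series({f"f{i}": 100.0 + i for i in range(len(y_rows))}),
        pd.DataFrame(y_rows, index=[f"f{i}" for i in range(len(y_rows))], columns=samples),
        nonnegative=False,
    )
    return em, ft


class TestCorrelatePairs:
    def test_perfect_correlation(self):
        x = [1, 2, 3, 4, 5, 6]
        em, ft = _paired([x], [[2 * v for v in x]], list("abcdef"))
        edges = correlate_pairs(em, ft)
        assert len(edges) == 1
        assert edges.loc[0, "r"] == pytest.approx(1.0)
        assert edges.loc[0, "p"] == 0.0

    def test_orthogonal_pair_filtered(self):
        # [1,-1,-1,1] is orthogonal to centered [1,2,3,4], so r = 0 exactly
        em, ft = _paired([[1, 2, 3, 4]], [[1, -1, -1, 1]], list("abcd"))
        edges = correlate_pairs(em, ft, min_abs_r=0.1)
        assert len(edges) == 0

    def test_p_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(42)
        samples = [f"s{i}" for i in range(12)]
        x = rng.normal(size=(3, 12))
        y = x[:2] + rng.normal(scale=0.7, size=(2, 12))
        em, ft = _paired(x, y, samples)
        edges = correlate_pairs(em, ft, min_abs_r=0.0)
        for row in edges.itertuples(index=False):
            xi = em.values.loc[row.transcript_id].to_numpy()
            yi = ft.abundance.loc[row.feature_id].to_numpy()
            r_ref, p_ref = stats.pearsonr(xi, yi)
            assert row.r == pytest.approx(r_ref, abs=1e-12)
            assert row.p == pytest.approx(p_ref, rel=1e-9)

    def test_strong_correlation_p_magnitude(self):
        # r = 0.744 at ~50 samples: the t-formula puts the two-sided p in
        # the 1e-10 .. 1e-9 decade, consistent with a reported 1.1e-10
        r = 0.744
        for n in (48, 53):
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = 2 * stats.t.sf(t, df=n - 2)
            assert 1e-12 < p < 1e-8


class TestMutualRank:
    @staticmethod
    def _brute_force(edges):
        mr = {}
        for row in edges.itertuples(index=False):
            by_t = edges[edges["transcript_id"] == row.transcript_id]["r"].abs()
            by_f = edges[edges["feature_id"] == row.feature_id]["r"].abs()
            rank_t = (by_t > abs(row.r)).sum() + ((by_t == abs(row.r)).sum() + 1) / 2.0
            rank_f = (by_f > abs(row.r)).sum() + ((by_f == abs(row.r)).sum() + 1) / 2.0
            mr[(row.transcript_id, row.feature_id)] = math.sqrt(rank_t * rank_f)
        return mr

    def test_reciprocal_best_pair_mr_one(self):
        edges = pd.DataFrame(
            {
                "transcript_id": ["t1", "t1", "t2"],
                "feature_id": ["f1", "f2", "f2"],
                "r": [0.99, 0.4, 0.5],
            }
        )
        out = mutual_rank(edges)
        row = out[(out.transcript_id == "t1") & (out.feature_id == "f1")]
        assert row["mr"].iloc[0] == pytest.approx(1.0)

    def test_rank_product_definition(self):
        # rank_t(f) = 2 and rank_f(t) = 8 must give mr = sqrt(16) = 4
        assert math.sqrt(2 * 8) == pytest.approx(4.0)
        edges = {"transcript_id": [], "feature_id": [], "r": []}
        # t0-f0: f0 is t0's 2nd-best partner; t0 is f0's 8th-best partner
        for i, r in enumerate([0.9, 0.8]):
            edges["transcript_id"].append("t0")
            edges["feature_id"].append(f"f{i}")
            edges["r"].append(r)
        for j in range(7):
            edges["transcript_id"].append(f"u{j}")
            edges["feature_id"].append("f1")
            edges["r"].append(0.99 - j * 0.01)
        df = mutual_rank(pd.DataFrame(edges))
        row = df[(df.transcript_id == "t0") & (df.feature_id == "f1")]
        assert row["mr"].iloc[0] == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_f = 15, 12
        rows = []
        for i in range(n_t):
            for j in range(n_f):
                if rng.random() < 0.4:
                    rows.append((f"t{i:02d}", f"f{j:02d}", rng.uniform(-1, 1)))
        edges = pd.DataFrame(rows, columns=["transcript_id", "feature_id", "r"])
        out = mutual_rank(edges)
        oracle = self._brute_force(edges)
        for row in out.itertuples(index=False):
            assert row.mr == pytest.approx(oracle[(row.transcript_id, row.feature_id)])

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        edges = pd.DataFrame(
            {
                "transcript_id": [f"t{i % 4}" for i in range(20)],
                "feature_id": [f"f{i % 5}" for i in range(20)],
                "r": rng.uniform(-1, 1, 20),
            }
        ).drop_duplicates(["transcript_id", "feature_id"])
        a = mutual_rank(edges).set_index(["transcript_id", "feature_id"])["mr"]
        b = (
            mutual_rank(edges.sample(frac=1, random_state=0))
            .set_index(["transcript_id", "feature_id"])["mr"]
        )
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


class TestDecayWeights:
    @staticmethod
    def _edges(mrs):
        return pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(len(mrs))],
                "feature_id": [f"f{i}" for i in range(len(mrs))],
                "r": [0.5] * len(mrs),
                "p": [0.01] * len(mrs),
                "mr": mrs,
            }
        )

    def test_mr_one_gives_weight_one_for_every_rate(self):
        nets = decay_weights(self._edges([1.0]))
        for dr, net in nets.items():
            assert net["weight"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_e_minus_one(self):
        nets = decay_weights(self._edges([11.0]), decay_rates=[10])
        assert nets[10]["weight"].iloc[0] == pytest.approx(math.exp(-1), abs=1e-12)

    def test_cutoff_boundary(self):
        # exp(-(mr-1)/10) = 0.01 at mr ~ 47.05
        nets = decay_weights(self._edges([47.05, 48.0]), decay_rates=[10], cutoff=0.01)
        kept = nets[10]
        assert kept["mr"].tolist() == [47.05]
        assert kept["weight"].iloc[0] == pytest.approx(0.01, abs=5e-5)

    def test_network_nesting(self):
        rng = np.random.default_rng(5)
        edges = self._edges(sorted(rng.uniform(1, 120, 200)))
        nets = decay_weights(edges, decay_rates=[5, 10, 25, 50], cutoff=0.01)
        sets = {
            dr: set(zip(net["transcript_id"], net["feature_id"]))
            for dr, net in nets.items()
        }
        assert sets[5] <= sets[10] <= sets[25] <= sets[50]
        assert len(sets[5]) < len(sets[50])  # nesting is strict on this span

    def test_nonpositive_rate_errors(self):
        with pytest.raises(ValidationError):
            decay_weights(self._edges([2.0]), decay_rates=[0])

    def test_weight_bounds_and_monotonicity(self):
        mrs = [1.0, 2.0, 5.0, 11.0, 20.0]
        nets = decay_weights(self._edges(mrs), decay_rates=[5, 50], cutoff=0.0)
        for dr, net in nets.items():
            w = net["weight"].to_numpy()
            assert ((w > 0) & (w <= 1)).all()
            assert (np.diff(w) < 0).all()  # strictly decreasing in mr
        assert (nets[50]["weight"].to_numpy()[1:] > nets[5]["weight"].to_numpy()[1:]).all()


def test_planted_pairs_outcorrelate_decoys(toy):
    """Parameter recovery: planted transcript-feature pairs reach higher
    mean |r| than decoy pairings under the latent induction profile."""
    em = toy.expression
    ft = toy.features
    edges = correlate_pairs(em, ft, min_abs_r=0.0)
    planted_t = set(toy.truth.transcript_ids)
    planted_f = set(toy.truth.feature_ids)
    planted = edges[
        edges.transcript_id.isin(planted_t) & edges.feature_id.isin(planted_f)
    ]["r"].abs()
    decoy = edges[
        ~(edges.transcript_id.isin(planted_t) | edges.feature_id.isin(planted_f))
    ]["r"].abs()
    assert planted.mean() > decoy.mean() + 0.3
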