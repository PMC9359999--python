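"""TPM computation, replicate averaging, ranking, heatmap transform."""

import numpy as np
import pandas as pd
import pytest

from metaminer.expression import (
    ExpressionError,
    ExpressionMatrix,
    average_replicates,
    compute_tpm,
    heatmap_matrix,
    top_abundant,
)


def _series(values, ids=None):
    ids = ids or [f"t{i}" for i in range(len(values))]
    return pd.Series(values, index=ids, dtype=float)


class TestComputeTpm:
    def test_two_transcripts_formula(self):
        tpm = compute_tpm(_series([10, 10]), _series([100, 200]))
        assert tpm.tolist() == pytest.approx([666666.6667, 333333.3333], rel=1e-6)

    def test_equal_counts_equal_lengths_split_evenly(self):
        n = 8
        tpm = compute_tpm(_series([5] * n), _series([300] * n))
        assert tpm.tolist() == pytest.approx([1e6 / n] * n)

    def test_random_samples_conserve_a_million(self):
        rng = np.random.default_rng(61)
        for _ in range(50):
            n = int(rng.integers(2, 200))
            counts = _series(rng.integers(0, 5000, size=n).astype(float))
            lengths = _series(rng.uniform(100, 3000, size=n))
            total = compute_tpm(counts, lengths).sum()
            if counts.sum() > 0:
                assert abs(total - 1e6) / 1e6 < 1e-6

    def test_all_zero_counts_give_all_zero_tpm(self):
        assert compute_tpm(_series([0, 0]), _series([100, 100])).sum() == 0.0

    def test_uniform_count_scaling_is_invariant(self):
        rng = np.random.default_rng(62)
        counts = _series(rng.integers(1, 1000, size=30).astype(float))
        lengths = _series(rng.uniform(200, 2000, size=30))
        base = compute_tpm(counts, lengths)
        scaled = compute_tpm(counts * 7.5, lengths)
        assert np.allclose(base, scaled)

    def test_nonpositive_length_is_fatal(self):
        with pytest.raises(ExpressionError, match="length"):
            compute_tpm(_series([1, 2]), _series([100, 0]))

    def test_mismatched_ids_are_fatal(self):
        with pytest.raises(ExpressionError, match="index"):
            compute_tpm(_series([1], ["a"]), _series([100], ["b"]))


def _matrix(counts_by_sample, lengths=None, tissues=None):
    counts = pd.DataFrame(counts_by_sample)
    lengths = pd.DataFrame(
        lengths
        if lengths is not None
        else {s: [100.0] * len(counts) for s in counts.columns},
    )
    lengths.index = counts.index
    samples = pd.DataFrame(
        {
            "tissue": tissues or [s.split("_")[0] for s in counts.columns],
            "replicate": list(range(1, len(counts.columns) + 1)),
        },
        index=counts.columns,
    )
    return ExpressionMatrix(counts=counts, lengths=lengths, samples=samples)


class TestAverageReplicates:
    def test_identical_replicates_average_to_themselves(self):
        m = _matrix({"leaf_r1": [10, 30], "leaf_r2": [10, 30]})
        mean = average_replicates(m)
        assert mean["leaf"].tolist() == pytest.approx(m.tpm["leaf_r1"].tolist())

    def test_zero_and_ten_average_to_five(self):
        m = _matrix({"leaf_r1": [0.0, 100.0], "leaf_r2": [10.0, 90.0]})
        tpm = m.tpm
        mean = average_replicates(m)
        expected = (tpm["leaf_r1"] + tpm["leaf_r2"]) / 2
        assert mean["leaf"].tolist() == pytest.approx(expected.tolist())

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(63)
        counts = {
            f"{t}_r{r}": rng.integers(0, 1000, size=40).astype(float)
            for t in ("leaf", "stem", "root")
            for r in (1, 2)
        }
        m = _matrix(counts)
        mean = average_replicates(m)
        tpm = m.tpm
        for tissue in ("leaf", "stem", "root"):
            cols = [c for c in counts if c.startswith(tissue)]
            for tid in tpm.index:
                manual = sum(tpm.loc[tid, c] for c in cols) / len(cols)
                assert mean.loc[tid, tissue] == pytest.approx(manual)


class TestTopAbundant:
    def _mean(self):
        return pd.DataFrame(
            {"leaf": [5.0, 9.0, 9.0, 1.0]},
            index=["t3", "t1", "t0", "t2"],
        )

    def test_unique_maximum_is_first(self):
        mean = pd.DataFrame({"leaf": [1.0, 7.0, 3.0]}, index=["a", "b", "c"])
        assert top_abundant(mean, 1, "leaf") == ["b"]

    def test_ties_break_lexicographically(self):
        assert top_abundant(self._mean(), 1, "leaf") == ["t0"]

    def test_top_n_is_prefix_of_top_n_plus_one(self):
        rng = np.random.default_rng(64)
        mean = pd.DataFrame(
            {"leaf": rng.uniform(0, 100, size=30)},
            index=[f"t{i}" for i in range(30)],
        )
        for n in range(1, 29):
            assert top_abundant(mean, n, "leaf") == top_abundant(mean, n + 1, "leaf")[:n]

    def test_overlong_request_warns_and_returns_all(self):
        with pytest.warns(UserWarning):
            got = top_abundant(self._mean(), 10, "leaf")
        assert len(got) == 4


class TestHeatmapMatrix:
    def test_zero_tpm_with_unit_pseudocount_is_zero(self):
        mean = pd.DataFrame({"leaf": [0.0]}, index=["t0"])
        assert heatmap_matrix(["t0"], mean).iloc[0, 0] == 0.0

    def test_seven_plus_one_is_three(self):
        mean = pd.DataFrame({"leaf": [7.0]}, index=["t0"])
        assert heatmap_matrix(["t0"], mean).iloc[0, 0] == 3.0

    def test_exponentiating_recovers_values(self):
        rng = np.random.default_rng(65)
        mean = pd.DataFrame(
            {t: rng.uniform(0, 1e4, size=25) for t in ("leaf", "stem", "root")},
            index=[f"t{i}" for i in range(25)],
        )
        heat = heatmap_matrix(list(mean.index), mean, pseudocount=1.0)
        assert np.abs(2.0**heat - (mean + 1.0)).max().max() < 1e-9

    def test_nonpositive_pseudocount_is_fatal(self):
        mean = pd.DataFrame({"leaf": [1.0]}, index=["t0"])
        with pytest.raises(ExpressionError):
            heatmap_matrix(["t0"], mean, pseudocount=0.0)


class TestOrderIndependence:
    def test_permuting_transcripts_permutes_outputs(self):
        rng = np.random.default_rng(66)
        counts = rng.integers(1, 500, size=20).astype(float)
        lengths = rng.uniform(100, 2000, size=20)
        ids = [f"t{i}" for i in range(20)]
        tpm = compute_tpm(_series(counts, ids), _series(lengths, ids))
        perm = rng.permutation(20)
        tpm_p = compute_tpm(
            _series(counts[perm], [ids[i] for i in perm]),
            _series(lengths[perm], [ids[i] for i in perm]),
        )
        for i in perm:
            assert tpm[ids[i]] == pytest.approx(tpm_p[ids[i]])
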