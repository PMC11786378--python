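import numpy as np
import pandas as pd
import pytest

from genediverse import simulate
from genediverse.diversity import (
    diversity_table,
    effective_isoform_count,
    isoform_proportions,
    mean_intertissue_divergence,
    mean_intratissue_entropy,
    mean_profile,
    tissue_entropy,
)
from genediverse.errors import SingleIsoformGeneError, UnexpressedGeneError
from genediverse.weights import WeightVector
from tests.conftest import make_tensor


def wv(d):
    return WeightVector(pd.Series(d, dtype=float), provenance="combined")


class TestTissueEntropy:
    def test_uniform_four_isoforms_two_bits(self):
        assert tissue_entropy([0.25, 0.25, 0.25, 0.25]) == pytest.approx(2.0)

    def test_single_isoform_zero_bits(self):
        assert tissue_entropy([1.0]) == pytest.approx(0.0)

    def test_hand_evaluated(self):
        # -(0.5 log2 0.5 + 2 * 0.25 log2 0.25) = 0.5 + 1.0
        assert tissue_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5)

    def test_zeros_skipped(self):
        assert tissue_entropy([0.5, 0.5, 0.0]) == pytest.approx(1.0)

    def test_negative_error(self):
        with pytest.raises(ValueError):
            tissue_entropy([1.5, -0.5])

    def test_oracle_scipy(self):
        from scipy.stats import entropy as scipy_entropy

        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = int(rng.integers(1, 8))
            x = rng.dirichlet(np.ones(k))
            assert tissue_entropy(x) == pytest.approx(
                float(scipy_entropy(x, base=2)), abs=1e-9
            )

    def test_bounded_by_log2_support(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            k = int(rng.integers(1, 10))
            x = rng.dirichlet(np.ones(k) * 0.5)
            h = tissue_entropy(x)
            assert -1e-12 <= h <= np.log2(k) + 1e-12


class TestEffectiveIsoformCount:
    def test_printed_conversions(self):
        assert round(effective_isoform_count(2.1), 1) == 4.3
        # 2**1.7 = 3.2490...; rounds to 3.2 (published 3.3 presumably used
        # an unrounded entropy value)
        assert round(effective_isoform_count(1.7), 1) == 3.2

    def test_zero_entropy_one_isoform(self):
        assert effective_isoform_count(0.0) == pytest.approx(1.0)

    def test_negative_error(self):
        with pytest.raises(ValueError):
            effective_isoform_count(-0.1)


class TestIsoformProportions:
    def test_basic(self):
        tensor = make_tensor(
            {"t1": [3.0], "t2": [1.0]}, ["A"], {"t1": "g", "t2": "g"}
        )
        x = isoform_proportions(tensor, "g", "A")
        assert x["t1"] == pytest.approx(0.75)
        assert x["t2"] == pytest.approx(0.25)

    def test_degenerate(self):
        tensor = make_tensor(
            {"t1": [5.0], "t2": [0.0], "t3": [0.0]},
            ["A"],
            {"t1": "g", "t2": "g", "t3": "g"},
        )
        x = isoform_proportions(tensor, "g", "A")
        assert list(x) == [1.0, 0.0, 0.0]

    def test_all_zero_signal(self):
        tensor = make_tensor({"t1": [0.0]}, ["A"], {"t1": "g"})
        with pytest.raises(UnexpressedGeneError):
            isoform_proportions(tensor, "g", "A")


class TestMeanIntratissueEntropy:
    def _tensor(self):
        # sample A: uniform over 4 isoforms (H=2); sample B: single (H=0)
        return make_tensor(
            {
                "t1": [1.0, 8.0],
                "t2": [1.0, 0.0],
                "t3": [1.0, 0.0],
                "t4": [1.0, 0.0],
            },
            ["A", "B"],
            {f"t{i}": "g" for i in range(1, 5)},
        )

    def test_equal_weights(self):
        h = mean_intratissue_entropy(self._tensor(), "g", wv({"A": 1.0, "B": 1.0}))
        assert h == pytest.approx(1.0)

    def test_zero_weight_sample_ignored(self):
        h = mean_intratissue_entropy(self._tensor(), "g", wv({"A": 1.0, "B": 0.0}))
        assert h == pytest.approx(2.0)

    def test_identical_profiles_any_weights(self):
        tensor = make_tensor(
            {"t1": [3.0, 6.0], "t2": [1.0, 2.0]},
            ["A", "B"],
            {"t1": "g", "t2": "g"},
        )
        for w in ({"A": 1.0, "B": 1.0}, {"A": 0.9, "B": 0.1}):
            h = mean_intratissue_entropy(tensor, "g", wv(w))
            assert h == pytest.approx(tissue_entropy([0.75, 0.25]))

    def test_single_isoform_excluded(self):
        tensor = make_tensor({"t1": [1.0, 2.0]}, ["A", "B"], {"t1": "g"})
        with pytest.raises(SingleIsoformGeneError):
            mean_intratissue_entropy(tensor, "g", wv({"A": 1.0, "B": 1.0}))

    def test_entropy_bounded_by_annotated_isoforms(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            m = int(rng.integers(2, 5))
            data = {f"t{i}": rng.uniform(0, 10, m) for i in range(k)}
            tensor = make_tensor(
                data, [f"S{j}" for j in range(m)], {f"t{i}": "g" for i in range(k)}
            )
            w = wv({f"S{j}": 1.0 for j in range(m)})
            h = mean_intratissue_entropy(tensor, "g", w)
            assert h <= np.log2(k) + 1e-9


class TestMeanProfile:
    def test_single_sample(self, two_sample_tensor):
        q = mean_profile(two_sample_tensor, "g1", wv({"A": 1.0, "B": 0.0}))
        assert q["t1"] == pytest.approx(1.0)

    def test_two_equal_samples(self, two_sample_tensor):
        q = mean_profile(two_sample_tensor, "g1", wv({"A": 1.0, "B": 1.0}))
        assert q["t1"] == pytest.approx(0.5)
        assert q["t2"] == pytest.approx(0.5)

    def test_sums_to_one(self):
        rng = np.random.default_rng(4)
        data = {f"t{i}": rng.uniform(0, 5, 3) for i in range(4)}
        tensor = make_tensor(
            data, ["A", "B", "C"], {f"t{i}": "g" for i in range(4)}
        )
        q = mean_profile(tensor, "g", wv({"A": 0.2, "B": 0.5, "C": 1.0}))
        assert q.sum() == pytest.approx(1.0, abs=1e-9)


class TestMeanIntertissueDivergence:
    def test_shared_profile_zero(self):
        tensor = make_tensor(
            {"t1": [3.0, 6.0], "t2": [1.0, 2.0]},
            ["A", "B"],
            {"t1": "g", "t2": "g"},
        )
        d = mean_intertissue_divergence(tensor, "g", wv({"A": 1.0, "B": 1.0}))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_profiles_one_bit(self, two_sample_tensor):
        d = mean_intertissue_divergence(
            two_sample_tensor, "g1", wv({"A": 1.0, "B": 1.0})
        )
        assert d == pytest.approx(1.0)

    def test_zero_weight_divergent_sample_ignored(self):
        tensor = make_tensor(
            {"t1": [3.0, 6.0, 0.0], "t2": [1.0, 2.0, 9.0]},
            ["A", "B", "C"],
            {"t1": "g", "t2": "g"},
        )
        base = mean_intertissue_divergence(tensor, "g", wv({"A": 1.0, "B": 1.0, "C": 0.0}))
        two = make_tensor(
            {"t1": [3.0, 6.0], "t2": [1.0, 2.0]},
            ["A", "B"],
            {"t1": "g", "t2": "g"},
        )
        ref = mean_intertissue_divergence(two, "g", wv({"A": 1.0, "B": 1.0}))
        assert base == pytest.approx(ref, abs=1e-12)

    def test_isoform_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        data = {f"t{i}": rng.uniform(0.1, 5, 3) for i in range(4)}
        w = wv({"A": 0.7, "B": 1.0, "C": 0.4})
        t1 = make_tensor(data, ["A", "B", "C"], {f"t{i}": "g" for i in range(4)})
        renamed = {f"iso{i}": data[f"t{i}"] for i in range(4)}
        t2 = make_tensor(renamed, ["A", "B", "C"], {f"iso{i}": "g" for i in range(4)})
        assert mean_intertissue_divergence(t1, "g", w) == pytest.approx(
            mean_intertissue_divergence(t2, "g", w), abs=1e-12
        )
        assert mean_intratissue_entropy(t1, "g", w) == pytest.approx(
            mean_intratissue_entropy(t2, "g", w), abs=1e-12
        )

    def test_oracle_brute_force(self):
        """Independent plain-Python evaluation of the weighted KL mean."""
        import math

        rng = np.random.default_rng(6)
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            m = int(rng.integers(2, 5))
            abund = rng.uniform(0.05, 5.0, size=(k, m))
            w_vals = rng.uniform(0.1, 1.0, size=m)
            samples = [f"S{j}" for j in range(m)]
            tensor = make_tensor(
                {f"t{i}": abund[i] for i in range(k)},
                samples,
                {f"t{i}": "g" for i in range(k)},
            )
            w = wv(dict(zip(samples, w_vals)))

            # oracle: explicit loops
            props = [[abund[i][j] / sum(abund[i2][j] for i2 in range(k)) for i in range(k)]
                     for j in range(m)]
            wsum = sum(w_vals)
            q = [sum(w_vals[j] * props[j][i] for j in range(m)) / wsum for i in range(k)]
            dkls = []
            for j in range(m):
                d = 0.0
                for i in range(k):
                    if props[j][i] > 0:
                        d += props[j][i] * math.log2(props[j][i] / q[i])
                dkls.append(d)
            expected = sum(w_vals[j] * dkls[j] for j in range(m)) / wsum

            got = mean_intertissue_divergence(tensor, "g", w)
            assert got == pytest.approx(expected, abs=1e-9)
            assert got >= -1e-12


class TestDuplicateSampleInvariance:
    def test_weighted_means_invariant(self):
        """Appending an exact duplicate of a sample as a zero-length
        cherry off the root leaves entropy and divergence unchanged."""
        from genediverse.tree import SampleTree
        from genediverse.weights import similarity_weights

        data = {"t1": [3.0, 1.0, 6.0], "t2": [1.0, 4.0, 2.0]}
        tensor = make_tensor(data, ["A", "B", "C"], {"t1": "g", "t2": "g"})
        tree = SampleTree.from_newick("(A:1,B:1,C:1);")
        w = similarity_weights(tree)
        h0 = mean_intratissue_entropy(tensor, "g", w)
        d0 = mean_intertissue_divergence(tensor, "g", w)

        dup = {"t1": [3.0, 1.0, 6.0, 3.0], "t2": [1.0, 4.0, 2.0, 1.0]}
        tensor2 = make_tensor(dup, ["A", "B", "C", "A2"], {"t1": "g", "t2": "g"})
        tree2 = SampleTree.from_newick("((A:0,A2:0):1,B:1,C:1);")
        w2 = similarity_weights(tree2)
        h1 = mean_intratissue_entropy(tensor2, "g", w2)
        d1 = mean_intertissue_divergence(tensor2, "g", w2)
        assert h1 == pytest.approx(h0, abs=1e-9)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestMonotoneRecovery:
    def test_divergence_increases_as_concentration_drops(self):
        medians = []
        for conc in (200.0, 5.0, 0.5):
            cfg = simulate.SimConfig(
                seed=9, n_genes=100, n_tissues=6, between_tissue_concentration=conc
            )
            tensor, tree = simulate.gen_isoform_tensor(cfg)
            df = diversity_table(tensor, tree)
            medians.append(df["mean_divergence_bits"].dropna().median())
        assert medians[0] < medians[1] < medians[2]

    def test_entropy_increases_with_isoform_count(self):
        meds = []
        for lam in (1.0, 6.0):
            cfg = simulate.SimConfig(
                seed=10,
                n_genes=80,
                n_tissues=6,
                isoform_count_params={"epigene": lam, "non_epigene": lam, "histone": lam},
                dirichlet_base_concentration=5.0,
            )
            tensor, tree = simulate.gen_isoform_tensor(cfg)
            df = diversity_table(tensor, tree)
            meds.append(df["mean_entropy_bits"].dropna().median())
        assert meds[0] < meds[1]


class TestDiversityTable:
    def test_single_isoform_flagged(self, small_tensor):
        tensor, tree = small_tensor
        df = diversity_table(tensor, tree)
        single = df[df["n_isoforms"] == 1]
        assert (single["excluded"]).all()
        assert (single["reason"] == "single_isoform").all()

    def test_effective_isoforms_consistent(self, small_tensor):
        tensor, tree = small_tensor
        df = diversity_table(tensor, tree).dropna(subset=["mean_entropy_bits"])
        np.testing.assert_allclose(
            df["effective_isoforms"], 2.0 ** df["mean_entropy_bits"], rtol=1e-12
        )
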