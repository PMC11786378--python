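import numpy as np
import pandas as pd
import pytest

from genediverse import simulate
from genediverse.temporal import (
    TemporalProfile,
    assign_genes,
    binned_time_weights,
    cluster_seed_genes,
    filter_by_range,
    impute_nearest,
    metacluster,
    prepare_profiles,
    scale_max,
    weighted_pearson,
)


def profile(data: dict, ages, subregion="SR1", units="TPM"):
    mat = pd.DataFrame.from_dict(data, orient="index", columns=list(ages)).astype(float)
    return TemporalProfile(subregion=subregion, ages=tuple(ages), matrix=mat, units=units)


class TestPrepareProfiles:
    def _long(self, rows):
        return pd.DataFrame(rows, columns=["subregion", "age_pcw", "gene", "value"])

    def test_same_age_averaged_then_rescaled(self):
        rows = [
            ("S", 8.0, "g1", 2.0),
            ("S", 8.0, "g1", 4.0),
            ("S", 8.0, "g2", 3.0),
        ] + [("S", a, "g1", 1.0) for a in (10.0, 12.0, 14.0, 16.0)] + [
            ("S", a, "g2", 1.0) for a in (10.0, 12.0, 14.0, 16.0)
        ]
        profiles = prepare_profiles(self._long(rows), min_timepoints=5)
        mat = profiles["S"].matrix
        # g1 at age 8: mean(2,4)=3 of total 6 -> half the column TPM
        assert mat.loc["g1", 8.0] == pytest.approx(5e5)

    def test_rpkm_to_tpm(self):
        rows = [("S", a, g, 1.0) for a in (8.0, 10.0, 12.0, 14.0, 16.0)
                for g in ("g1", "g2")]
        profiles = prepare_profiles(self._long(rows), min_timepoints=5)
        assert profiles["S"].matrix.loc["g1", 8.0] == pytest.approx(5e5)

    def test_too_few_timepoints_dropped(self):
        rows = [("S", a, "g1", 1.0) for a in (8.0, 10.0, 12.0, 14.0)]
        assert prepare_profiles(self._long(rows), min_timepoints=5) == {}

    def test_max_age_cut(self):
        rows = [("S", a, "g1", 1.0) for a in (8.0, 10.0, 12.0, 14.0, 16.0, 45.0)]
        profiles = prepare_profiles(self._long(rows), min_timepoints=5)
        assert 45.0 not in profiles["S"].ages


class TestFilterByRange:
    def test_constant_gene_dropped(self):
        p = profile({"flat": [1.0] * 5, "var": [0.0, 1.0, 2.0, 3.0, 4.0]},
                    [8, 10, 12, 14, 16])
        kept, dropped = filter_by_range(p, min_range=0.5)
        assert dropped == ["flat"]
        assert list(kept.matrix.index) == ["var"]

    def test_exact_threshold_retained(self):
        p = profile({"edge": [0.0, 0.5, 0.0, 0.0, 0.0]}, [8, 10, 12, 14, 16])
        kept, dropped = filter_by_range(p, min_range=0.5)
        assert dropped == []

    def test_generated_flat_class_all_dropped(self):
        cfg = simulate.SimConfig(
            seed=6,
            n_genes=20,
            trajectory_params={
                "class_fractions": {"flat": 1.0},
                "noise_sd": 0.0,
                "n_subregions": 1,
                "ages": (8.0, 10.0, 14.0, 20.0, 30.0),
            },
        )
        samples, truth = simulate.gen_temporal_profiles(cfg)
        # raw generated trajectories have range exactly 0
        for gene, grp in samples.groupby("gene"):
            assert grp["value"].max() - grp["value"].min() == pytest.approx(0.0)


class TestScaleMax:
    def test_divides_by_max(self):
        p = profile({"g": [1.0, 2.0, 4.0, 1.0, 1.0]}, [8, 10, 12, 14, 16])
        out = scale_max(p)
        assert list(out.matrix.loc["g"]) == pytest.approx([0.25, 0.5, 1.0, 0.25, 0.25])

    def test_already_scaled_identity(self):
        p = profile({"g": [0.5, 1.0, 0.5, 0.2, 0.1]}, [8, 10, 12, 14, 16])
        out = scale_max(p)
        assert out.matrix.loc["g"].max() == pytest.approx(1.0)

    def test_negative_error(self):
        p = profile({"g": [0.5, 1.0, 0.5, 0.2, 0.1]}, [8, 10, 12, 14, 16],
                    units="scaled")
        p.matrix.iloc[0, 0] = -0.5
        with pytest.raises(ValueError):
            scale_max(p)


class TestBinnedTimeWeights:
    def test_two_nonempty_bins(self):
        w = binned_time_weights([8.0, 9.0, 38.0])
        assert w[8.0] == pytest.approx(0.25)
        assert w[9.0] == pytest.approx(0.25)
        assert w[38.0] == pytest.approx(0.5)

    def test_one_age_per_bin(self):
        w = binned_time_weights([5.0, 15.0, 25.0, 35.0])
        assert all(v == pytest.approx(0.25) for v in w)

    def test_all_in_one_bin_uniform(self):
        w = binned_time_weights([2.0, 4.0, 6.0])
        assert all(v == pytest.approx(1 / 3) for v in w)

    def test_sums_to_one_random(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ages = sorted(set(np.round(rng.uniform(0.5, 40.0, rng.integers(2, 12)), 2)))
            assert binned_time_weights(ages).sum() == pytest.approx(1.0)

    def test_out_of_span_error(self):
        with pytest.raises(ValueError):
            binned_time_weights([45.0])


class TestWeightedPearson:
    def test_uniform_reduces_to_pearson(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(3, 10))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            got = weighted_pearson(x, y, np.ones(n))
            expected = float(np.corrcoef(x, y)[0, 1])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert weighted_pearson(x, 2 * x + 1, np.ones(4)) == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0])
        assert weighted_pearson(x, -x, np.array([0.2, 0.5, 0.3])) == pytest.approx(-1.0)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            weighted_pearson([1.0, 1.0], [1.0, 2.0], [1.0, 1.0])

    def test_oracle_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            n = int(rng.integers(2, 8))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 2.0, size=n)
            # independent evaluation via explicit sums
            W = w.sum()
            mx = sum(w[i] * x[i] for i in range(n)) / W
            my = sum(w[i] * y[i] for i in range(n)) / W
            cov = sum(w[i] * (x[i] - mx) * (y[i] - my) for i in range(n)) / W
            vx = sum(w[i] * (x[i] - mx) ** 2 for i in range(n)) / W
            vy = sum(w[i] * (y[i] - my) ** 2 for i in range(n)) / W
            if vx <= 0 or vy <= 0:
                continue
            expected = cov / np.sqrt(vx * vy)
            assert weighted_pearson(x, y, w) == pytest.approx(expected, abs=1e-9)


class TestClusterAndAssign:
    ages = (5.0, 12.0, 18.0, 25.0, 32.0, 38.0)

    def _profile(self):
        t = np.linspace(0, 1, len(self.ages))
        data = {
            "up1": 0.2 + 0.8 * t,
            "up2": 0.25 + 0.75 * t,
            "down1": 1.0 - 0.8 * t,
            "down2": 0.95 - 0.75 * t,
            "near_up": 0.22 + 0.78 * t,
            "noise": np.array([0.9, 0.1, 0.8, 0.2, 0.7, 0.3]),
        }
        return profile(data, self.ages, units="scaled")

    def test_identical_trajectories_one_cluster(self):
        t = np.linspace(0, 1, len(self.ages))
        p = profile({"a": 0.1 + t, "b": 0.1 + t}, self.ages, units="scaled")
        cs = cluster_seed_genes(p, ["a", "b"])
        assert len(cs.clusters) == 1

    def test_anticorrelated_two_clusters(self):
        t = np.linspace(0, 1, len(self.ages))
        p = profile({"a": 0.1 + t, "b": 1.1 - t}, self.ages, units="scaled")
        cs = cluster_seed_genes(p, ["a", "b"], cut=0.2)
        assert len(cs.clusters) == 2

    def test_assignment(self):
        p = self._profile()
        cs = cluster_seed_genes(p, ["up1", "up2", "down1", "down2"], cut=0.2)
        assert len(cs.clusters) == 2
        cs = assign_genes(cs, p, threshold=0.8)
        assigned = {
            g: cid for cid, info in cs.clusters.items() for g in info["assigned"]
        }
        up_cluster = next(
            cid for cid, info in cs.clusters.items() if "up1" in info["seed"]
        )
        assert assigned.get("near_up") == up_cluster
        assert "noise" not in assigned

    def test_gene_equal_to_mean_correlation_one(self):
        p = self._profile()
        cs = cluster_seed_genes(p, ["up1", "down1"], cut=0.2)
        mean_up = cs.means.loc[
            next(cid for cid, info in cs.clusters.items() if "up1" in info["seed"])
        ]
        extra = p.matrix.copy()
        extra.loc["clone"] = mean_up
        p2 = profile({g: extra.loc[g].to_numpy() for g in extra.index},
                     self.ages, units="scaled")
        cs2 = cluster_seed_genes(p2, ["up1", "down1"], cut=0.2)
        cs2 = assign_genes(cs2, p2, threshold=0.8)
        all_assigned = {
            g: r for info in cs2.clusters.values() for g, r in info["assigned"].items()
        }
        assert all_assigned["clone"] == pytest.approx(1.0)

    def test_threshold_strict(self):
        # correlation exactly at the threshold is NOT assigned
        p = self._profile()
        cs = cluster_seed_genes(p, ["up1", "up2"], cut=0.2)
        cs = assign_genes(cs, p, threshold=1.0)  # nothing can exceed 1.0
        assert all(not info["assigned"] for info in cs.clusters.values())


class TestImputeNearest:
    def test_nearest(self):
        traj = pd.Series({8.0: 1.0, 20.0: 5.0})
        out = impute_nearest(traj, [10.0])
        assert out[10.0] == 1.0

    def test_tie_takes_earlier(self):
        traj = pd.Series({8.0: 1.0, 20.0: 5.0})
        assert impute_nearest(traj, [14.0])[14.0] == 1.0

    def test_identity_on_same_grid(self):
        traj = pd.Series({8.0: 1.0, 20.0: 5.0})
        out = impute_nearest(traj, [8.0, 20.0])
        assert list(out) == [1.0, 5.0]


class TestMetacluster:
    def test_identical_means_merge(self):
        t = np.linspace(0, 1, 5)
        ages = (6.0, 14.0, 22.0, 30.0, 38.0)
        cs = []
        for sr in ("S1", "S2"):
            p = profile({"a": 0.1 + t, "b": 0.12 + t}, ages, subregion=sr,
                        units="scaled")
            cs.append(cluster_seed_genes(p, ["a", "b"]))
        table = metacluster(cs, cut=0.2)
        assert table["metacluster"].nunique() == 1

    def test_opposite_means_split(self):
        t = np.linspace(0, 1, 5)
        ages = (6.0, 14.0, 22.0, 30.0, 38.0)
        p1 = profile({"a": 0.1 + t, "b": 0.12 + t}, ages, subregion="S1",
                     units="scaled")
        p2 = profile({"a": 1.1 - t, "b": 1.12 - t}, ages, subregion="S2",
                     units="scaled")
        cs = [cluster_seed_genes(p1, ["a", "b"]), cluster_seed_genes(p2, ["a", "b"])]
        table = metacluster(cs, cut=0.2)
        assert table["metacluster"].nunique() == 2

    def test_too_few_error(self):
        t = np.linspace(0, 1, 5)
        ages = (6.0, 14.0, 22.0, 30.0, 38.0)
        p = profile({"a": 0.1 + t, "b": 0.12 + t}, ages, units="scaled")
        with pytest.raises(ValueError):
            metacluster([cluster_seed_genes(p, ["a", "b"])])


class TestClassRecovery:
    def test_planted_classes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = simulate.SimConfig(
            seed=21,
            n_genes=60,
            trajectory_params={
                "class_fractions": {
                    "increasing": 1 / 3,
                    "decreasing": 1 / 3,
                    "oscillating": 1 / 3,
                },
                "noise_sd": 0.02,
                "n_subregions": 3,
                "ages": (8.0, 9.0, 12.0, 16.0, 21.0, 24.0, 35.0, 37.0),
            },
        )
        samples, truth = simulate.gen_temporal_profiles(cfg)
        profiles = prepare_profiles(samples, min_timepoints=5)
        assert len(profiles) == 3
        cluster_sets = []
        for p in profiles.values():
            kept, _ = filter_by_range(p, min_range=0.5)
            scaled = scale_max(kept)
            cs = cluster_seed_genes(scaled, list(scaled.matrix.index), cut=0.2)
            cluster_sets.append(cs)
            labels = {
                g: cid for cid, info in cs.clusters.items() for g in info["seed"]
            }
            genes = sorted(labels)
            ari = adjusted_rand_score(
                [truth.loc[g, "trajectory_class"] for g in genes],
                [labels[g] for g in genes],
            )
            assert ari >= 0.9
        # metaclusters align with planted classes across subregions
        table = metacluster(cluster_sets, cut=0.2)
        rep_class = []
        for _, row in table.iterrows():
            cs = next(c for c in cluster_sets if c.subregion == row["subregion"])
            seed_gene = cs.clusters[row["cluster"]]["seed"][0]
            rep_class.append(truth.loc[seed_gene, "trajectory_class"])
        ari_meta = adjusted_rand_score(rep_class, list(table["metacluster"]))
        assert ari_meta >= 0.9


class TestDeterminism:
    def test_pipeline_deterministic(self):
        cfg = simulate.SimConfig(seed=30, n_genes=30)
        s1, _ = simulate.gen_temporal_profiles(cfg)
        s2, _ = simulate.gen_temporal_profiles(cfg)
        pd.testing.assert_frame_equal(s1, s2)
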