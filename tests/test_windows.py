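"""Window statistics against brute-force oracles; outliers; permutation engine."""

import numpy as np
import pandas as pd
import pytest

from hybridkit.vcfio import GenotypeMatrix
from hybridkit.windows import (
    WindowSpec,
    call_outliers,
    genes_in_windows,
    intersection_permutation,
    make_windows,
    window_statistics,
)


def gm_from_dosage(dosage, scaffolds, positions, samples=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    sites = pd.DataFrame({"scaffold": scaffolds, "pos": positions,
                          "ref": "A", "alt": "T"})
    samples = samples or [f"I{i}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage)


def brute_window_stats(dosage, positions, idx_a, idx_b, start, end, n_geno):
    """Independent per-site loop: pi for both panels, dxy, Hudson FST."""
    pi_a = pi_b = dxy = num = den = 0.0
    for j, pos in enumerate(positions):
        if not (start <= pos <= end):
            continue
        for panel, acc in ((idx_a, "a"), (idx_b, "b")):
            pass
        da = dosage[idx_a, j]
        db = dosage[idx_b, j]
        da = da[da != -1]
        db = db[db != -1]
        na, nb = 2 * len(da), 2 * len(db)
        if na >= 2:
            pa = da.sum() / na
            pi_a += 2 * pa * (1 - pa) * na / (na - 1)
        if nb >= 2:
            pb = db.sum() / nb
            pi_b += 2 * pb * (1 - pb) * nb / (nb - 1)
        if na >= 2 and nb >= 2:
            pa, pb = da.sum() / na, db.sum() / nb
            d = pa * (1 - pb) + pb * (1 - pa)
            dxy += d
            den += d
            num += (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    fst = num / den if den else np.nan
    return pi_a / n_geno, pi_b / n_geno, dxy / n_geno, fst


class TestWindowStatistics:
    def test_single_segregating_site_hand_computed(self):
        # p = 0.5 from 4 allele copies: site pi term = 2*0.25*(4/3) = 2/3,
        # the mean pairwise difference (8 of 12 pairs differ)
        dosage = np.array([[1], [1]])
        gm = gm_from_dosage(dosage, ["s1"], [500])
        stats = window_statistics(
            gm, {"P": ["I0", "I1"]}, WindowSpec(1000, 1000, 1),
            callability={"s1": np.arange(1, 1001)})
        assert stats.loc[0, "pi_P"] == pytest.approx((2 / 3) / 1000)

    def test_fixed_difference_terms(self):
        dosage = np.array([[0], [0], [2], [2]])
        gm = gm_from_dosage(dosage, ["s1"], [10])
        stats = window_statistics(
            gm, {"A": ["I0", "I1"], "B": ["I2", "I3"]},
            WindowSpec(100, 100, 1), callability={"s1": np.arange(1, 101)})
        assert stats.loc[0, "dxy_A_B"] == pytest.approx(1 / 100)
        assert stats.loc[0, "fst_A_B"] == pytest.approx(1.0)

    def test_identical_panels_fst_near_zero(self, rng):
        # same allele frequencies in both panels: numerator is unbiased for 0
        n_sites = 2000
        p = rng.uniform(0.2, 0.8, n_sites)
        d = rng.binomial(2, p, size=(40, n_sites)).astype(np.int8)
        gm = gm_from_dosage(d, ["s1"] * n_sites, np.arange(1, n_sites + 1))
        samples = gm.samples
        stats = window_statistics(
            gm, {"A": samples[:20], "B": samples[20:]},
            WindowSpec(n_sites, n_sites, 1),
            callability={"s1": np.arange(1, n_sites + 1)})
        assert abs(stats.loc[0, "fst_A_B"]) < 0.01

    def test_matches_brute_force_random_instance(self, rng):
        n_sites, n_samples = 200, 9
        scaffolds = np.repeat(["c1", "c2", "c3"], [80, 70, 50])
        positions = np.concatenate([
            np.sort(rng.choice(5000, 80, replace=False)) + 1,
            np.sort(rng.choice(5000, 70, replace=False)) + 1,
            np.sort(rng.choice(5000, 50, replace=False)) + 1,
        ])
        dosage = rng.integers(-1, 3, size=(n_samples, n_sites)).astype(np.int8)
        gm = gm_from_dosage(dosage, scaffolds, positions)
        panels = {"A": gm.samples[:5], "B": gm.samples[5:]}
        call = {c: np.arange(1, 5001) for c in ("c1", "c2", "c3")}
        spec = WindowSpec(2000, 1000, 1)
        stats = window_statistics(gm, panels, spec, callability=call,
                                  scaffold_lengths={c: 5000 for c in ("c1", "c2", "c3")})
        idx_a, idx_b = np.arange(5), np.arange(5, 9)
        for _, row in stats.iterrows():
            smask = scaffolds == row["scaffold"]
            pi_a, pi_b, dxy, fst = brute_window_stats(
                dosage[:, smask], positions[smask], idx_a, idx_b,
                row["start"], row["end"], row["n_genotyped"])
            assert row["pi_A"] == pytest.approx(pi_a, abs=1e-12)
            assert row["pi_B"] == pytest.approx(pi_b, abs=1e-12)
            assert row["dxy_A_B"] == pytest.approx(dxy, abs=1e-12)
            if np.isnan(fst):
                assert np.isnan(row["fst_A_B"])
            else:
                assert row["fst_A_B"] == pytest.approx(fst, abs=1e-12)

    def test_sample_order_invariance(self, rng):
        dosage = rng.integers(0, 3, size=(8, 100)).astype(np.int8)
        gm = gm_from_dosage(dosage, ["s1"] * 100, np.arange(1, 101))
        panels1 = {"A": ["I0", "I1", "I2", "I3"], "B": ["I4", "I5", "I6", "I7"]}
        panels2 = {"A": ["I3", "I1", "I0", "I2"], "B": ["I7", "I5", "I6", "I4"]}
        call = {"s1": np.arange(1, 101)}
        s1 = window_statistics(gm, panels1, WindowSpec(100, 100, 1), call)
        s2 = window_statistics(gm, panels2, WindowSpec(100, 100, 1), call)
        pd.testing.assert_frame_equal(s1, s2)

    def test_under_minimum_marked_invalid(self):
        dosage = np.array([[1], [0], [1], [2]])
        gm = gm_from_dosage(dosage, ["s1"], [50])
        stats = window_statistics(
            gm, {"A": ["I0", "I1"], "B": ["I2", "I3"]},
            WindowSpec(100, 100, 60), callability={"s1": np.arange(1, 51)})
        assert not stats.loc[0, "valid"]

    def test_fst_recovers_simulation_divergence(self, ten_scaffold_layout):
        # Balding-Nichols panels at F=0.25: genome-wide Hudson FST ~ 0.25
        from hybridkit import sim
        f = 0.25
        fr = sim.build_species_frequencies(ten_scaffold_layout, 20_000, fst=f,
                                           prop_diagnostic=0.0, seed=41)
        da = sim.sample_parental_genotypes(fr, "A", 15, seed=42)
        db = sim.sample_parental_genotypes(fr, "B", 15, seed=43)
        gm = gm_from_dosage(np.vstack([da, db]),
                            fr.sites["scaffold"], fr.sites["pos"])
        panels = {"A": gm.samples[:15], "B": gm.samples[15:]}
        stats = window_statistics(gm, panels, WindowSpec(1_000_000, 1_000_000, 1),
                                  scaffold_lengths=ten_scaffold_layout.lengths)
        # ratio of genome-wide sums: weight windows by their dxy denominator
        mean_fst = np.nansum(stats["fst_A_B"] * stats["dxy_A_B"]) / np.nansum(stats["dxy_A_B"])
        assert mean_fst == pytest.approx(f, abs=0.025)


class TestWindowsGeometry:
    def test_sliding_layout_and_truncation(self):
        w = make_windows({"s1": 250}, WindowSpec(100, 50, 1))
        assert list(zip(w["start"], w["end"])) == [(1, 100), (51, 150), (101, 200), (151, 250)]
        assert not w["truncated"].any()
        w2 = make_windows({"s1": 120}, WindowSpec(100, 50, 1))
        assert w2.iloc[-1]["truncated"]


class TestOutliers:
    def _stats(self, fst_values):
        n = len(fst_values)
        return pd.DataFrame({
            "scaffold": "s1", "start": np.arange(n) * 10 + 1,
            "end": np.arange(n) * 10 + 100, "n_genotyped": 100,
            "fst_A_B": fst_values, "valid": True,
        })

    def test_five_percent_called(self):
        stats = self._stats(np.linspace(0, 1, 100))
        out = call_outliers(stats, ("A", "B"), 95)
        assert len(out.windows) >= 5
        assert (out.windows["fst_A_B"] >= out.threshold).all()

    def test_constant_fst_all_tie(self):
        stats = self._stats(np.full(50, 0.3))
        out = call_outliers(stats, ("A", "B"), 95)
        assert len(out.windows) == 50

    def test_outlier_fraction_close_to_percentile(self, rng):
        stats = self._stats(rng.normal(0.3, 0.1, size=5000))
        out = call_outliers(stats, ("A", "B"), 95)
        assert len(out.windows) / 5000 == pytest.approx(0.05, abs=0.005)

    def test_all_invalid_is_error(self):
        stats = self._stats(np.linspace(0, 1, 30))
        stats["valid"] = False
        with pytest.raises(ValueError):
            call_outliers(stats, ("A", "B"))


class TestGenesInWindows:
    def test_containment_and_other_scaffold(self):
        windows = pd.DataFrame({"scaffold": ["s1"], "start": [100], "end": [200]})
        genes = pd.DataFrame({
            "scaffold": ["s1", "s1", "s2"],
            "start": [120, 300, 120], "end": [180, 400, 180],
            "gene_id": ["inside", "outside", "wrong_scaffold"],
        })
        hit = genes_in_windows(windows, genes)
        assert list(hit["gene_id"]) == ["inside"]

    def test_one_bp_overlap_counts(self):
        windows = pd.DataFrame({"scaffold": ["s1"], "start": [100], "end": [200]})
        genes = pd.DataFrame({"scaffold": ["s1", "s1"], "start": [200, 201],
                              "end": [250, 250], "gene_id": ["touch", "miss"]})
        assert list(genes_in_windows(windows, genes)["gene_id"]) == ["touch"]

    def test_matches_all_pairs_oracle(self, rng):
        windows = pd.DataFrame({
            "scaffold": rng.choice(["c1", "c2"], 50),
            "start": rng.integers(1, 5000, 50)})
        windows["end"] = windows["start"] + rng.integers(10, 500, 50)
        genes = pd.DataFrame({
            "scaffold": rng.choice(["c1", "c2"], 80),
            "start": rng.integers(1, 5000, 80)})
        genes["end"] = genes["start"] + rng.integers(10, 300, 80)
        genes["gene_id"] = [f"g{i}" for i in range(80)]
        hit = set(genes_in_windows(windows, genes)["gene_id"])
        oracle = set()
        for _, g in genes.iterrows():
            for _, w in windows.iterrows():
                if g["scaffold"] == w["scaffold"] and g["start"] <= w["end"] and w["start"] <= g["end"]:
                    oracle.add(g["gene_id"])
        assert hit == oracle


class TestIntersectionPermutation:
    def test_full_set_intersects_everything(self):
        res = intersection_permutation((100, 30), 100, observed=10, n_reps=50, seed=1)
        assert res["min"] == res["max"] == 30

    def test_pigeonhole_lower_bound(self):
        res = intersection_permutation((70, 60), 100, observed=30, n_reps=100, seed=2)
        assert res["min"] >= 30  # n1 + n2 - N

    def test_mean_matches_hypergeometric(self):
        res = intersection_permutation((2575, 2569, ), 13330, observed=1601,
                                       n_reps=400, seed=3)
        closed = 2575 * 2569 / 13330
        assert res["expected_closed_form"] == pytest.approx(closed)
        assert res["mean"] == pytest.approx(closed, rel=0.02)
        assert res["p_ge_observed"] == 0.0  # 1601 shared windows is far beyond chance

    def test_observed_larger_than_sets_rejected(self):
        with pytest.raises(ValueError):
            intersection_permutation((10, 20), 100, observed=15, n_reps=10)

    def test_three_way_draws(self):
        res = intersection_permutation((50, 60, 70), 100, observed=10, n_reps=200, seed=4)
        closed = 100 * 0.5 * 0.6 * 0.7
        assert res["mean"] == pytest.approx(closed, rel=0.15)
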