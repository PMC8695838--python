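"""Ancestry states, tract extraction rules, and genome-wide summaries."""

import numpy as np
import pandas as pd
import pytest

from hybridkit import sim
from hybridkit.painting import ClassifierThresholds, find_fixed_sites, hybrid_profile
from hybridkit.tracts import (
    AncestryStates,
    extract_tracts,
    naive_paint,
    read_haplotype_ancestry,
    states_from_truth,
    summarize_ancestry,
    tract_length_histogram,
)
from hybridkit.vcfio import GenotypeMatrix


def states_one_scaffold(arr, kind="haplotype", positions=None):
    arr = np.asarray(arr, dtype=np.int8)
    pos = positions if positions is not None else np.arange(1, len(arr) + 1)
    sites = pd.DataFrame({"scaffold": "s1", "pos": pos})
    return AncestryStates(kind=kind, sites=sites, states={"h": arr})


class TestExtractTracts:
    def test_constant_state_single_tract(self):
        ts = extract_tracts(states_one_scaffold(np.zeros(30)))
        assert len(ts.tracts) == 1
        row = ts.tracts.iloc[0]
        assert (row["n_snps"], row["state"]) == (30, "A")
        assert row["bp"] == 30

    def test_alternating_states_one_tract_each(self):
        arr = np.tile([0, 1], 15)
        ts = extract_tracts(states_one_scaffold(arr))
        assert len(ts.tracts) == 30
        assert (ts.tracts["n_snps"] == 1).all()
        assert (ts.tracts["bp"] == 1).all()  # single-SNP tract is 1 bp

    def test_scaffold_end_breaks_tract(self):
        sites = pd.DataFrame({"scaffold": ["s1"] * 10 + ["s2"] * 10,
                              "pos": list(range(1, 11)) * 2})
        st = AncestryStates(kind="haplotype", sites=sites,
                            states={"h": np.zeros(20, dtype=np.int8)})
        ts = extract_tracts(st)
        assert len(ts.tracts) == 2
        assert set(ts.tracts["scaffold"]) == {"s1", "s2"}

    def test_missing_bridges_by_default_breaks_on_request(self):
        arr = np.array([0, 0, -1, 0, 0], dtype=np.int8)
        bridged = extract_tracts(states_one_scaffold(arr))
        assert len(bridged.tracts) == 1
        broken = extract_tracts(states_one_scaffold(arr), bridge_missing=False)
        assert len(broken.tracts) == 2

    def test_snp_counts_sum_to_called_total(self, rng):
        arr = rng.choice([-1, 0, 1], size=200, p=[0.1, 0.45, 0.45]).astype(np.int8)
        ts = extract_tracts(states_one_scaffold(arr))
        assert ts.tracts["n_snps"].sum() == (arr != -1).sum()

    def test_scaffold_order_invariance(self, rng):
        n = 100
        sites1 = pd.DataFrame({"scaffold": ["s1"] * 50 + ["s2"] * 50,
                               "pos": list(range(1, 51)) * 2})
        arr = rng.integers(0, 2, n).astype(np.int8)
        st1 = AncestryStates("haplotype", sites1, {"h": arr})
        # same data with scaffolds swapped in order
        sites2 = pd.DataFrame({"scaffold": ["s2"] * 50 + ["s1"] * 50,
                               "pos": list(range(1, 51)) * 2})
        st2 = AncestryStates("haplotype", sites2,
                             {"h": np.concatenate([arr[50:], arr[:50]])})
        s1 = summarize_ancestry(extract_tracts(st1), st1)
        s2 = summarize_ancestry(extract_tracts(st2), st2)
        for col in ("prop_B", "n_tracts", "n_transitions", "mean_tract_bp"):
            assert s1.loc[0, col] == s2.loc[0, col]


class TestNaivePaint:
    def _world(self):
        dosage = np.array([
            [0, 0, 0],
            [2, 2, 2],
            [1, 1, 1],   # F1
            [0, 2, -1],  # mixed homozygous + missing
        ], dtype=np.int8)
        sites = pd.DataFrame({"scaffold": "s1", "pos": [10, 20, 30],
                              "ref": "A", "alt": "T"})
        gm = GenotypeMatrix(samples=["A1", "B1", "F1", "X"], sites=sites, dosage=dosage)
        fixed = find_fixed_sites(gm, ["A1"], ["B1"])
        return gm, fixed

    def test_pure_and_f1_states(self):
        gm, fixed = self._world()
        assert (naive_paint(gm, fixed, "A1").states["A1"] == 0).all()
        assert (naive_paint(gm, fixed, "F1").states["F1"] == 1).all()

    def test_mixed_states_with_missing(self):
        gm, fixed = self._world()
        np.testing.assert_array_equal(naive_paint(gm, fixed, "X").states["X"], [0, 2, -1])

    def test_summary_agrees_with_hybrid_profile(self, cohort):
        gm = GenotypeMatrix(samples=cohort.samples,
                            sites=cohort.freqs.sites.assign(ref="A", alt="T"),
                            dosage=cohort.dosage)
        panels = cohort.panels
        fixed = find_fixed_sites(gm, panels["A"], panels["B"], allow_missing_fraction=0.3)
        t = ClassifierThresholds(min_sites=10, min_completeness=0.0)
        for s in panels["admixed"]:
            states = naive_paint(gm, fixed, s)
            summary = summarize_ancestry(extract_tracts(states), states)
            prof = hybrid_profile(gm, fixed, s, t)
            assert summary.loc[0, "prop_B"] == pytest.approx(prof.hybrid_index)
            assert summary.loc[0, "ancestry_heterozygosity"] == pytest.approx(
                prof.heterozygosity)


class TestHaplotypeMatrixIO:
    def test_roundtrip_from_simulator(self, cohort, tmp_path):
        paths = sim.emit_dataset(cohort, str(tmp_path / "c"), seed=61)
        states = read_haplotype_ancestry(paths["ancestry"])
        truth = states_from_truth(cohort)
        assert set(states.states) == set(truth.states)
        for k in states.states:
            np.testing.assert_array_equal(states.states[k], truth.states[k])

    def test_constant_column_single_run(self, cohort, tmp_path):
        paths = sim.emit_dataset(cohort, str(tmp_path / "c"), seed=62)
        states = read_haplotype_ancestry(paths["ancestry"])
        ts = extract_tracts(states)
        f1_a = ts.tracts[ts.tracts["id"] == "F1_1_h1"]
        # pure haplotype: exactly one tract per scaffold with data
        assert len(f1_a) == f1_a["scaffold"].nunique()

    def test_shuffled_rows_rejected(self, cohort, tmp_path):
        paths = sim.emit_dataset(cohort, str(tmp_path / "c"), seed=63)
        df = pd.read_csv(paths["ancestry"], sep="\t")
        df = df.sample(frac=1, random_state=0)
        bad = tmp_path / "shuffled.tsv"
        df.to_csv(bad, sep="\t", index=False)
        with pytest.raises(ValueError, match="increasing"):
            read_haplotype_ancestry(str(bad))

    def test_non_binary_values_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("scaffold\tpos\th1\ns1\t1\tA\ns1\t2\tQ\n")
        with pytest.raises(ValueError, match="non-binary"):
            read_haplotype_ancestry(str(p))


class TestSummaries:
    def test_f1_truth_summary(self, small_layout, mixed_freqs):
        ds = sim.simulate_dataset(small_layout, mixed_freqs, {},
                                  [("f1", sim.PedigreeSpec(kind="F1"))], seed=64)
        states = states_from_truth(ds)
        summary = summarize_ancestry(extract_tracts(states), states)
        props = dict(zip(summary["id"], summary["prop_B"]))
        assert sorted(props.values()) == [0.0, 1.0]  # one pure-A, one pure-B haplotype
        assert (summary["n_transitions"] == 0).all()

    def test_bc1_ancestry_proportion(self, ten_scaffold_layout):
        rng = np.random.default_rng(65)
        fr = sim.build_species_frequencies(ten_scaffold_layout, 2000, fst=0.3,
                                           prop_diagnostic=1.0, seed=rng)
        props = []
        for r in range(60):
            ds = sim.simulate_dataset(
                ten_scaffold_layout, fr, {},
                [("bc", sim.PedigreeSpec(kind="BC1", backcross_to="A"))], seed=rng)
            states = states_from_truth(ds)
            s = summarize_ancestry(extract_tracts(states), states)
            props.append(s["prop_A"].mean())  # diploid mean over both haplotypes
        se = np.std(props) / np.sqrt(len(props))
        assert np.mean(props) == pytest.approx(0.75, abs=3 * se)

    def test_tract_bp_proportion_matches_snp_proportion(self, cohort):
        states = states_from_truth(cohort)
        ts = extract_tracts(states)
        summary = summarize_ancestry(ts, states)
        for _, row in summary.iterrows():
            sub = ts.tracts[ts.tracts["id"] == row["id"]]
            bp_b = sub.loc[sub["state"] == "B", "bp"].sum() / sub["bp"].sum()
            # bp-weighted and SNP-weighted proportions agree up to discretization
            assert bp_b == pytest.approx(row["prop_B"], abs=0.06)

    def test_truth_recovery_improves_with_site_density(self, small_layout):
        rng = np.random.default_rng(66)
        errors = []
        for n_sites in (50, 500, 5000):
            fr = sim.build_species_frequencies(small_layout, n_sites, fst=0.3,
                                               prop_diagnostic=1.0, seed=123)
            errs = []
            for r in range(15):
                ds = sim.simulate_dataset(
                    small_layout, fr, {},
                    [("lg", sim.PedigreeSpec(kind="later_generation", g=4))], seed=rng)
                states = states_from_truth(ds)
                s = summarize_ancestry(extract_tracts(states), states)
                est = s["prop_A"].mean()
                errs.append(abs(est - ds.truth[0].prop_a))
            errors.append(np.mean(errs))
        assert errors[2] < errors[0]

    def test_mean_tract_length_nonincreasing_in_generations(self, small_layout):
        rng = np.random.default_rng(67)
        fr = sim.build_species_frequencies(small_layout, 3000, fst=0.3,
                                           prop_diagnostic=1.0, seed=321)
        means = []
        for g in (1, 4, 8):
            vals = []
            for r in range(50):
                ds = sim.simulate_dataset(
                    small_layout, fr, {},
                    [("lg", sim.PedigreeSpec(kind="later_generation", g=g))], seed=rng)
                states = states_from_truth(ds)
                ts = extract_tracts(states)
                vals.append(ts.tracts["bp"].mean())
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]

    def test_histogram_counts_cover_all_tracts(self, cohort):
        states = states_from_truth(cohort)
        ts = extract_tracts(states)
        hist = tract_length_histogram(ts, bins=20)
        assert hist["count"].sum() == len(ts.tracts)
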