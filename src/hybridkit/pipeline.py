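"""Config-driven orchestration of the full analysis, plus a synthetic demo.

A run either simulates a cohort (``simulate`` block) or ingests real files
(``inputs`` block), then executes the toggled stages in dataflow order:
ingest/filter → ancestry painting and classification → window statistics,
outliers and the overlap permutation → f3 tests → ancestry tracts. Every
output TSV starts with comment headers recording the package version, the
seed and the estimator choices, so two runs with the same config and seed
produce byte-identical bundles.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import sim
from .f3 import admixture_test, f3_with_jackknife
from .painting import ClassifierThresholds, find_fixed_sites, hybrid_profile, profile_table
from .tracts import extract_tracts, states_from_truth, summarize_ancestry, tract_length_histogram
from .vcfio import SiteFilterConfig, filter_sites, read_panel_table, read_vcf
from .windows import WindowSpec, call_outliers, intersection_permutation, window_statistics

__all__ = ["RunConfig", "load_config", "run", "demo_end_to_end"]

log = logging.getLogger("hybridkit")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: str
    seed: int = 0
    # exactly one of the two input modes
    inputs: dict | None = None  # vcf, panels, optional gff / allsites / ancestry_matrix
    simulate: dict | None = None
    stages: list[str] = field(default_factory=lambda: ["paint", "windows", "f3", "tracts"])
    max_depth: int = 450
    max_missing: float = 0.20
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    window: WindowSpec = field(default_factory=WindowSpec)
    percentile: float = 95.0
    permutation_reps: int = 1000
    z_threshold: float = -3.0
    snps_per_block: int = 500
    painting_pair: tuple[str, str] | None = None  # species mapped to scale 0 and 1
    f3_targets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("config must set exactly one of 'inputs' and 'simulate'")
        known = {"simulate", "paint", "windows", "f3", "tracts"}
        for s in self.stages:
            if s not in known:
                raise ValueError(f"unknown stage {s!r}; known: {sorted(known)}")


def load_config(path: str) -> RunConfig:
    """Parse a YAML config file into a validated RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("thresholds", "window"):
        if key in raw and isinstance(raw[key], dict):
            cls = ClassifierThresholds if key == "thresholds" else WindowSpec
            raw[key] = cls(**raw[key])
    if "painting_pair" in raw and raw["painting_pair"] is not None:
        raw["painting_pair"] = tuple(raw["painting_pair"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def _header_lines(cfg: RunConfig, extra: dict | None = None) -> str:
    fields = {"version": __version__, "seed": cfg.seed, **(extra or {})}
    return "".join(f"# hybridkit {k}={v}\n" for k, v in fields.items())


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(cfg, extra))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _default_simulate_block(seed: int) -> dict:
    """Three-species world with F1, reciprocal BC1 and later-generation hybrids."""
    return {
        "n_scaffolds": 20,
        "scaffold_bp": 500_000,
        # ~1 crossover per scaffold per meiosis: the genome is a miniature,
        # so the density is scaled up to keep recombination visible
        "morgans_per_bp": 2e-6,
        "n_sites": 20_000,
        "fst": 0.25,
        "prop_diagnostic": 0.10,
        "species": ["A", "B", "C"],
        "focal_pair": ["A", "B"],
        "panel_sizes": {"A": 6, "B": 6, "C": 4},
        "missing_rate": 0.02,
        "with_depth": True,
        "pedigrees": [
            {"sample": "hyb_F1", "kind": "F1"},
            {"sample": "hyb_BC1_A", "kind": "BC1", "backcross_to": "A"},
            {"sample": "hyb_BC1_B", "kind": "BC1", "backcross_to": "B"},
            {"sample": "hyb_BC2_A", "kind": "BCn", "backcross_to": "A", "n": 2},
            {"sample": "hyb_BC2_B", "kind": "BCn", "backcross_to": "B", "n": 2},
            {"sample": "hyb_LG4", "kind": "later_generation", "g": 4},
            {"sample": "hyb_LG6", "kind": "later_generation", "g": 6},
        ],
        "seed": seed,
    }


def _simulate(cfg: RunConfig, outdir: Path) -> tuple[sim.SimulatedDataset, dict[str, str]]:
    blk = dict(cfg.simulate)
    layout = sim.GenomeLayout(
        scaffolds=tuple((f"scaffold_{i + 1}", int(blk.get("scaffold_bp", 1_000_000)))
                        for i in range(int(blk.get("n_scaffolds", 10)))),
        morgans_per_bp=float(blk.get("morgans_per_bp", 1e-8)),
    )
    rng = np.random.default_rng(blk.get("seed", cfg.seed))
    freqs = sim.build_species_frequencies(
        layout, int(blk.get("n_sites", 20_000)), float(blk.get("fst", 0.25)),
        float(blk.get("prop_diagnostic", 0.10)), rng,
        species=tuple(blk.get("species", ("A", "B"))),
        focal_pair=tuple(blk["focal_pair"]) if "focal_pair" in blk else None,
    )
    pedigrees = []
    for p in blk.get("pedigrees", []):
        p = dict(p)
        sid = p.pop("sample")
        pair = tuple(p.pop("pair", freqs.focal_pair))
        pedigrees.append((sid, sim.PedigreeSpec(pair=pair, **p)))
    ds = sim.simulate_dataset(
        layout, freqs, dict(blk.get("panel_sizes", {"A": 5, "B": 5})), pedigrees,
        seed=rng, missing_rate=float(blk.get("missing_rate", 0.0)),
        with_depth=bool(blk.get("with_depth", False)),
    )
    paths = sim.emit_dataset(ds, str(outdir / "sim"), seed=rng)
    log.info("simulated %d samples x %d sites -> %s",
             len(ds.samples), freqs.n_sites, paths["vcf"])
    return ds, paths


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns a report dict of DataFrames/paths.

    Fails before any stage runs when a referenced sample is absent from the
    genotype data or the panel table, naming the offending sample.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"outdir": str(outdir)}

    sim_ds = None
    if config.simulate is not None:
        sim_ds, paths = _simulate(config, outdir)
        report["sim_paths"] = paths
        vcf_path = paths["vcf"]
        species_of = sim_ds.species_of
    else:
        vcf_path = config.inputs["vcf"]
        species_of = read_panel_table(config.inputs["panels"])

    gm = read_vcf(vcf_path)
    missing = [s for s in species_of if s not in gm.samples]
    if missing:
        raise ValueError(f"panel table references samples absent from the VCF: {missing}")
    n_before = gm.n_sites
    gm = filter_sites(gm, SiteFilterConfig(config.max_depth, config.max_missing))
    log.info("site filters: %d -> %d sites (depth<=%d, missing<=%.0f%%)",
             n_before, gm.n_sites, config.max_depth, 100 * config.max_missing)
    report["n_sites_ingested"], report["n_sites_filtered"] = n_before, gm.n_sites

    panels: dict[str, list[str]] = {}
    for s, sp in species_of.items():
        if sp not in ("admixed", "unknown"):
            panels.setdefault(sp, []).append(s)
    admixed = [s for s, sp in species_of.items() if sp == "admixed"]
    pair = config.painting_pair or tuple(list(panels)[:2])

    if "paint" in config.stages:
        fixed = find_fixed_sites(gm, panels[pair[0]], panels[pair[1]],
                                 species0=pair[0], species1=pair[1])
        log.info("fixed sites between %s and %s: %d", pair[0], pair[1], len(fixed))
        painted = panels[pair[0]] + panels[pair[1]] + admixed
        profiles = [hybrid_profile(gm, fixed, s, config.thresholds, painted_samples=painted)
                    for s in painted]
        table = profile_table(profiles, fixed)
        _write_tsv(table, outdir / "classification.tsv", config,
                   {"orientation": f"0={pair[0]},1={pair[1]}", "n_fixed_sites": len(fixed)})
        report["classification"] = table
        report["fixed_sites"] = fixed

    if "windows" in config.stages:
        lengths = (sim_ds.layout.lengths if sim_ds is not None else None)
        stats = window_statistics(gm, panels, config.window, callability=None,
                                  scaffold_lengths=lengths)
        _write_tsv(stats, outdir / "window_stats.tsv", config,
                   {"fst_estimator": "hudson_ratio_of_averages",
                    "window": config.window.window_bp, "step": config.window.step_bp})
        report["window_stats"] = stats
        outliers = {}
        perms = []
        for a, b in combinations(panels, 2):
            try:
                outliers[(a, b)] = call_outliers(stats, (a, b), config.percentile)
            except ValueError as exc:
                log.warning("outliers %s-%s skipped: %s", a, b, exc)
        for (p1, p2) in combinations(outliers, 2):
            o1, o2 = outliers[p1], outliers[p2]
            key1 = o1.windows["scaffold"].astype(str) + ":" + o1.windows["start"].astype(str)
            key2 = o2.windows["scaffold"].astype(str) + ":" + o2.windows["start"].astype(str)
            observed = len(set(key1) & set(key2))
            n_valid = int(stats["valid"].sum())
            res = intersection_permutation((len(o1.windows), len(o2.windows)),
                                           n_valid, observed, config.permutation_reps,
                                           np.random.default_rng(config.seed))
            perms.append({"pair1": f"{p1[0]}-{p1[1]}", "pair2": f"{p2[0]}-{p2[1]}",
                          "observed": observed, "perm_mean": res["mean"],
                          "perm_min": res["min"], "perm_max": res["max"],
                          "expected_closed_form": res["expected_closed_form"],
                          "p_ge_observed": res["p_ge_observed"]})
        if outliers:
            out_rows = pd.concat(
                [o.windows.assign(pair=f"{k[0]}-{k[1]}", threshold=o.threshold)
                 for k, o in outliers.items()], ignore_index=True)
            _write_tsv(out_rows, outdir / "outlier_windows.tsv", config,
                       {"percentile": config.percentile})
            report["outliers"] = outliers
        if perms:
            perm_df = pd.DataFrame(perms)
            _write_tsv(perm_df, outdir / "outlier_overlap_permutation.tsv", config,
                       {"n_reps": config.permutation_reps})
            report["permutation"] = perm_df

    if "f3" in config.stages:
        target_names = config.f3_targets or (["admixed"] if admixed else [])
        rows = []
        for tname in target_names:
            tsamples = admixed if tname == "admixed" else panels.get(tname, [])
            if len(tsamples) < 1:
                continue
            for a, b in combinations([p for p in panels if p != tname], 2):
                res = f3_with_jackknife(gm, panels[a], panels[b], tsamples,
                                        pops=(a, b, tname),
                                        snps_per_block=config.snps_per_block)
                row = res.row()
                row["verdict"] = admixture_test(res, config.z_threshold)
                rows.append(row)
        if rows:
            f3_df = pd.DataFrame(rows)
            _write_tsv(f3_df, outdir / "f3_tests.tsv", config,
                       {"estimator": "f3_with_target_sample_correction",
                        "jackknife": f"weighted_block_{config.snps_per_block}snp",
                        "z_threshold": config.z_threshold})
            report["f3"] = f3_df

    if "tracts" in config.stages:
        if sim_ds is not None and sim_ds.hap_ancestry:
            states = states_from_truth(sim_ds)
        elif config.inputs and config.inputs.get("ancestry_matrix"):
            from .tracts import read_haplotype_ancestry
            states = read_haplotype_ancestry(config.inputs["ancestry_matrix"])
        else:
            states = None
            log.warning("tracts stage skipped: no phased ancestry source")
        if states is not None:
            tset = extract_tracts(states)
            summary = summarize_ancestry(tset, states)
            _write_tsv(tset.tracts, outdir / "ancestry_tracts.tsv", config)
            _write_tsv(summary, outdir / "ancestry_summary.tsv", config)
            _write_tsv(tract_length_histogram(tset), outdir / "tract_histogram.tsv", config)
            report["tracts"] = tset
            report["tract_summary"] = summary

    return report


def demo_end_to_end(seed: int = 0, outdir: str = "hybridkit_demo") -> dict:
    """Full synthetic workflow: simulate a three-species world with known
    hybrids, then classify, window-scan, f3-test and tract-summarize it."""
    # depth cap scaled to the simulated coverage (21 samples x ~30x => ~630 summed)
    cfg = RunConfig(outdir=outdir, seed=seed, simulate=_default_simulate_block(seed),
                    stages=["paint", "windows", "f3", "tracts"],
                    window=WindowSpec(100_000, 10_000, 50),
                    max_depth=1500,
                    painting_pair=("A", "B"),
                    f3_targets=["admixed", "C"])
    return run(cfg)


def setup_logging(verbose: bool = True, logfile: str | None = None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s",
                        handlers=handlers, force=True)
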