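"""Sliding-window π, d_xy and Hudson F_ST, outlier windows, and overlap tests.

Per-site estimators use unbiased sample-frequency forms: within-population
diversity π sums 2·p̂(1−p̂)·n/(n−1) over variant sites, between-population
divergence d_xy sums p̂_A(1−p̂_B) + p̂_B(1−p̂_A), and F_ST is the
Hudson/Bhatia ratio-of-averages — the window numerator
(p̂_A−p̂_B)² − p̂_A(1−p̂_A)/(n_A−1) − p̂_B(1−p̂_B)/(n_B−1) summed over sites,
divided by the summed d_xy terms. π and d_xy are normalized by the count of
genotyped sites (variant + invariant) in the window, so an all-sites
callability source is required. Negative per-window F_ST values are retained
(no clamping) so genome-wide means stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "WindowSpec",
    "OutlierSet",
    "make_windows",
    "site_frequencies",
    "window_statistics",
    "call_outliers",
    "genes_in_windows",
    "intersection_permutation",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry and the validity floor on genotyped sites."""

    window_bp: int = 100_000
    step_bp: int = 10_000
    min_genotyped: int = 20_000

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step must not exceed window size")
        if self.min_genotyped > self.window_bp:
            raise ValueError("min genotyped sites cannot exceed window size")


@dataclass
class OutlierSet:
    """Windows at or above the F_ST percentile threshold for one pair."""

    pair: tuple[str, str]
    threshold: float
    percentile: float
    windows: pd.DataFrame
    genes: pd.DataFrame | None = None


def make_windows(scaffold_lengths: dict[str, int], spec: WindowSpec) -> pd.DataFrame:
    """Enumerate sliding windows per scaffold from position 1.

    Trailing windows shorter than the window size are emitted with
    ``truncated = True`` so edge effects stay visible downstream.
    """
    rows = []
    for scaf, length in scaffold_lengths.items():
        start = 1
        while start <= length:
            end = min(start + spec.window_bp - 1, length)
            rows.append((scaf, start, end, end - start + 1 < spec.window_bp))
            if end == length:
                break
            start += spec.step_bp
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "truncated"])


def site_frequencies(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample alt-allele frequency p̂ and allele-copy count n per site.

    ``dosage`` is a panel slice (samples × sites, −1 missing). Sites with no
    called genotype get n = 0 and p̂ = NaN.
    """
    called = dosage != -1
    n = 2 * called.sum(axis=0)
    ac = np.where(called, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, ac / n, np.nan)
    return p, n


def _pair_terms(pa, na, pb, nb):
    """Per-site d_xy and Hudson numerator terms; NaN where a panel lacks 2 copies."""
    ok = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dxy = pa * (1 - pb) + pb * (1 - pa)
        num = ((pa - pb) ** 2
               - pa * (1 - pa) / (na - 1)
               - pb * (1 - pb) / (nb - 1))
    dxy = np.where(ok, dxy, np.nan)
    num = np.where(ok, num, np.nan)
    return dxy, num


def window_statistics(
    gm,
    panels: dict[str, list[str]],
    spec: WindowSpec = WindowSpec(),
    callability=None,
    pairs: list[tuple[str, str]] | None = None,
    scaffold_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Window-wise π per panel and d_xy/F_ST per panel pair.

    ``panels`` maps population label → sample ids (≥2 samples each for
    meaningful estimates). ``callability`` is a per-scaffold mapping to
    sorted genotyped positions, a precomputed per-window count array, or
    None, in which case every window position is assumed genotyped (the
    window bp span is used; appropriate only for fully called simulations).
    Windows under the genotyped-site floor are marked invalid.
    """
    for name, members in panels.items():
        if len(members) < 2:
            raise ValueError(f"panel {name!r} needs >=2 samples for window statistics")
    pairs = pairs if pairs is not None else list(combinations(panels, 2))

    freq = {}
    for name, members in panels.items():
        freq[name] = site_frequencies(gm.dosage[gm.sample_index(members)])

    # per-site terms over the full site table, NaN where undefined
    pi_terms = {}
    for name, (p, n) in freq.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            t = 2 * p * (1 - p) * n / (n - 1)
        pi_terms[name] = np.where(n >= 2, t, np.nan)
    pair_dxy, pair_num = {}, {}
    for a, b in pairs:
        pa, na = freq[a]
        pb, nb = freq[b]
        pair_dxy[(a, b)], pair_num[(a, b)] = _pair_terms(pa, na, pb, nb)

    if scaffold_lengths is None:
        scaffold_lengths = _scaffold_extents(gm, callability)
    windows = make_windows(scaffold_lengths, spec)

    if callability is None:
        n_geno = (windows["end"] - windows["start"] + 1).to_numpy()
    elif isinstance(callability, dict):
        from .vcfio import genotyped_sites_per_window
        n_geno = genotyped_sites_per_window(callability, windows)
    else:
        n_geno = np.asarray(callability)
        if len(n_geno) != len(windows):
            raise ValueError("per-window callability length does not match window count")

    # window sums via per-scaffold cumulative sums over site positions
    out = {name: np.full(len(windows), np.nan) for name in panels}
    out_dxy = {pr: np.full(len(windows), np.nan) for pr in pairs}
    out_fst = {pr: np.full(len(windows), np.nan) for pr in pairs}

    site_scaf = gm.sites["scaffold"].to_numpy()
    site_pos = gm.sites["pos"].to_numpy()
    for scaf in windows["scaffold"].unique():
        smask = site_scaf == scaf
        pos = site_pos[smask]
        wmask = (windows["scaffold"] == scaf).to_numpy()
        lo = np.searchsorted(pos, windows.loc[wmask, "start"].to_numpy(), "left")
        hi = np.searchsorted(pos, windows.loc[wmask, "end"].to_numpy(), "right")

        def wsum(terms: np.ndarray) -> np.ndarray:
            c = np.concatenate([[0.0], np.nancumsum(terms[smask])])
            return c[hi] - c[lo]

        for name in panels:
            out[name][wmask] = wsum(pi_terms[name])
        for pr in pairs:
            dxy_sum = wsum(pair_dxy[pr])
            num_sum = wsum(pair_num[pr])
            out_dxy[pr][wmask] = dxy_sum
            with np.errstate(invalid="ignore", divide="ignore"):
                out_fst[pr][wmask] = np.where(dxy_sum != 0, num_sum / dxy_sum, np.nan)

    df = windows.copy()
    df["n_genotyped"] = n_geno
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in panels:
            df[f"pi_{name}"] = np.where(n_geno > 0, out[name] / n_geno, np.nan)
        for a, b in pairs:
            df[f"dxy_{a}_{b}"] = np.where(n_geno > 0, out_dxy[(a, b)] / n_geno, np.nan)
            df[f"fst_{a}_{b}"] = out_fst[(a, b)]
    df["valid"] = n_geno >= spec.min_genotyped
    return df


def _scaffold_extents(gm, callability) -> dict[str, int]:
    """Scaffold lengths for windowing: last site (or callable) position per scaffold."""
    extents: dict[str, int] = {}
    for scaf, grp in gm.sites.groupby("scaffold", sort=False):
        extents[scaf] = int(grp["pos"].max())
    if isinstance(callability, dict):
        for scaf, pos in callability.items():
            pos = np.asarray(pos)
            if pos.size:
                extents[scaf] = max(extents.get(scaf, 0), int(pos.max()))
    return extents


def call_outliers(stats: pd.DataFrame, pair: tuple[str, str],
                  percentile: float = 95.0) -> OutlierSet:
    """Windows with F_ST at or above the empirical percentile threshold."""
    col = f"fst_{pair[0]}_{pair[1]}"
    if col not in stats.columns:
        col_rev = f"fst_{pair[1]}_{pair[0]}"
        if col_rev not in stats.columns:
            raise KeyError(f"no F_ST column for pair {pair}")
        col = col_rev
    valid = stats[stats["valid"] & np.isfinite(stats[col])]
    if len(valid) < 20:
        raise ValueError(f"need >=20 valid windows to call outliers, have {len(valid)}")
    threshold = float(np.percentile(valid[col], percentile))
    return OutlierSet(pair=pair, threshold=threshold, percentile=percentile,
                      windows=valid[valid[col] >= threshold].reset_index(drop=True))


def genes_in_windows(windows: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping any window by at least 1 bp (1-based inclusive)."""
    trees: dict[str, IntervalTree] = {}
    for scaf, grp in windows.groupby("scaffold", sort=False):
        # half-open tree intervals: [start, end+1)
        trees[scaf] = IntervalTree.from_tuples(
            (int(s), int(e) + 1) for s, e in zip(grp["start"], grp["end"]))
    hit = [
        scaf in trees and bool(trees[scaf].overlap(int(s), int(e) + 1))
        for scaf, s, e in zip(genes["scaffold"], genes["start"], genes["end"])
    ]
    return genes[np.asarray(hit, dtype=bool)].reset_index(drop=True)


def intersection_permutation(
    n_draws: tuple[int, ...],
    universe: int,
    observed: int,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Null distribution of the overlap between random feature sets.

    Each replicate draws ``n_draws[k]`` items uniformly without replacement
    from a universe of ``universe`` items (10-kb windows or annotated genes)
    and records the size of the joint intersection; for two sets the
    closed-form expectation is the hypergeometric mean n1·n2/N. The empirical
    p-value is the fraction of replicates with an intersection at least as
    large as ``observed`` (greater-or-equal tail).
    """
    if any(n > universe for n in n_draws):
        raise ValueError("cannot draw more items than the universe holds")
    if len(n_draws) < 2:
        raise ValueError("need at least two set sizes")
    if observed > min(n_draws):
        raise ValueError("observed intersection exceeds the smallest set")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sizes = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        inter: np.ndarray | None = None
        for n in n_draws:
            draw = rng.choice(universe, size=n, replace=False)
            inter = draw if inter is None else np.intersect1d(inter, draw, assume_unique=True)
        sizes[r] = inter.size
    expected = universe * np.prod([n / universe for n in n_draws])
    return {
        "mean": float(sizes.mean()),
        "min": int(sizes.min()),
        "max": int(sizes.max()),
        "p_ge_observed": float((sizes >= observed).mean()),
        "expected_closed_form": float(expected),
        "observed": observed,
        "n_reps": n_reps,
        "distribution": sizes,
    }
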