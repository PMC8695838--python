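"""Three-population admixture statistic f3(C; A, B) with block-jackknife errors.

For target population C and sources A and B, the per-site term is
``(ĉ−â)(ĉ−b̂) − ĉ(1−ĉ)/(n_C−1)`` where â, b̂, ĉ are sample allele
frequencies and n_C the number of non-missing allele copies in C; the
correction removes the upward bias contributed by sampling variance of ĉ,
which enters both factors of the product (A and B enter one factor each, so
their sampling noise cancels in expectation). f3 is the mean term over
analyzed sites. A significantly negative f3 — Z strictly below −3 under a
weighted delete-one block jackknife — indicates C is admixed between
relatives of A and B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd

from .windows import site_frequencies

__all__ = [
    "F3Result",
    "f3_site_terms",
    "f3",
    "make_blocks",
    "block_jackknife",
    "admixture_test",
]


@dataclass
class F3Result:
    """Point estimate with jackknife uncertainty for one (C; A, B) test."""

    pop_a: str
    pop_b: str
    pop_c: str
    f3: float
    se: float | None = None
    z: float | None = None
    n_sites: int = 0
    n_blocks: int = 0
    site_terms: np.ndarray | None = None
    site_index: np.ndarray | None = None

    def row(self) -> dict:
        """Table-3-style row: A, B, C, f3, SE, Z, number of sites."""
        return {"A": self.pop_a, "B": self.pop_b, "C": self.pop_c,
                "f3": self.f3, "SE": self.se, "Z": self.z, "n_sites": self.n_sites}


def f3_site_terms(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                  n_c: np.ndarray | float) -> np.ndarray:
    """Per-site f3 terms from allele frequencies, with the C-sample correction.

    Pass ``n_c = np.inf`` for the population-frequency (infinite-sample)
    limit, where the correction vanishes.
    """
    a, b, c = map(np.asarray, (a, b, c))
    n_c = np.asarray(n_c, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(np.isinf(n_c), 0.0, c * (1 - c) / (n_c - 1))
    return (c - a) * (c - b) - corr


def f3(gm, panel_a: list[str], panel_b: list[str], panel_c: list[str],
       pops: tuple[str, str, str] = ("A", "B", "C"),
       drop_monomorphic: bool = True) -> F3Result:
    """Point estimate of f3(C; A, B) from a genotype matrix.

    A site is analyzed when every panel has at least one non-missing diploid
    (so C has ≥2 allele copies for the correction). Sites monomorphic for
    the same allele across all three panels are excluded by default — they
    carry no information and would only dilute the mean.
    """
    for name, panel in zip(pops, (panel_a, panel_b, panel_c)):
        if not panel:
            raise ValueError(f"panel {name!r} is empty")
    pa, na = site_frequencies(gm.dosage[gm.sample_index(panel_a)])
    pb, nb = site_frequencies(gm.dosage[gm.sample_index(panel_b)])
    pc, nc = site_frequencies(gm.dosage[gm.sample_index(panel_c)])

    ok = (na >= 2) & (nb >= 2) & (nc >= 2)
    if drop_monomorphic:
        with np.errstate(invalid="ignore"):
            mono = ((pa == 0) & (pb == 0) & (pc == 0)) | ((pa == 1) & (pb == 1) & (pc == 1))
        ok &= ~mono
    idx = np.flatnonzero(ok)
    terms = f3_site_terms(pa[idx], pb[idx], pc[idx], nc[idx])
    return F3Result(
        pop_a=pops[0], pop_b=pops[1], pop_c=pops[2],
        f3=float(terms.mean()) if idx.size else np.nan,
        n_sites=int(idx.size), site_terms=terms, site_index=idx,
    )


def make_blocks(sites: pd.DataFrame, site_index: np.ndarray,
                snps_per_block: int = 500, n_blocks: int | None = None,
                scaffold_blocks_min: int = 20) -> np.ndarray:
    """Assign analyzed sites to contiguous jackknife blocks.

    Default scheme: one block per scaffold when the data span at least
    ``scaffold_blocks_min`` scaffolds (blocks then respect linkage breaks),
    else contiguous ``snps_per_block``-SNP chunks. ``n_blocks`` forces a
    fixed number of equal contiguous chunks instead. Returns an int block id
    per analyzed site.
    """
    m = len(site_index)
    if n_blocks is not None:
        if n_blocks < 2:
            raise ValueError("need at least 2 blocks")
        return np.minimum((np.arange(m) * n_blocks) // m, n_blocks - 1)
    scafs = sites["scaffold"].to_numpy()[site_index]
    uniq = pd.unique(scafs)
    if len(uniq) >= scaffold_blocks_min:
        mapping = {s: i for i, s in enumerate(uniq)}
        return np.array([mapping[s] for s in scafs])
    return np.arange(m) // snps_per_block


def block_jackknife(site_terms: np.ndarray, block_ids: np.ndarray) -> tuple[float, float]:
    """Weighted delete-one-block jackknife standard error of the mean term.

    Blocks are weighted by their site counts (Busing-style weighted
    jackknife, the convention of the standard f-statistics toolkits), so
    unequal blocks — e.g. one block per scaffold — are handled exactly.
    Returns ``(se, z)``; a degenerate zero-variance input yields se = 0 and
    a signed infinite Z with a warning.
    """
    terms = np.asarray(site_terms, dtype=float)
    block_ids = np.asarray(block_ids)
    blocks = np.unique(block_ids)
    m = len(blocks)
    if m < 2:
        raise ValueError("block jackknife needs at least 2 blocks")
    n = terms.size
    total = terms.sum()
    theta = total / n

    sizes = np.array([(block_ids == b).sum() for b in blocks], dtype=float)
    bsums = np.array([terms[block_ids == b].sum() for b in blocks])
    theta_del = (total - bsums) / (n - sizes)  # delete-one-block means
    h = n / sizes
    theta_jack = m * theta - ((1 - sizes / n) * theta_del).sum()
    tau = h * theta - (h - 1) * theta_del
    var = ((tau - theta_jack) ** 2 / (h - 1)).sum() / m
    se = sqrt(max(var, 0.0))
    if se == 0.0:
        warnings.warn("zero jackknife variance; Z reported as signed infinity")
        z = np.inf if theta > 0 else (-np.inf if theta < 0 else np.nan)
    else:
        z = theta / se
    return se, z


def f3_with_jackknife(gm, panel_a, panel_b, panel_c,
                      pops: tuple[str, str, str] = ("A", "B", "C"),
                      snps_per_block: int = 500,
                      n_blocks: int | None = None,
                      drop_monomorphic: bool = True) -> F3Result:
    """f3 point estimate plus block-jackknife SE and Z in one call."""
    res = f3(gm, panel_a, panel_b, panel_c, pops, drop_monomorphic)
    blocks = make_blocks(gm.sites, res.site_index, snps_per_block, n_blocks)
    res.n_blocks = int(len(np.unique(blocks)))
    res.se, res.z = block_jackknife(res.site_terms, blocks)
    return res


def admixture_test(result: F3Result, z_threshold: float = -3.0) -> str:
    """Verdict from the Z score: ``admixed`` iff Z strictly below the threshold."""
    if result.z is None or np.isnan(result.z):
        raise ValueError("result has no finite Z score; run the jackknife first")
    return "admixed" if result.z < z_threshold else "not_supported"
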