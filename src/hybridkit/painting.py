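"""Diagnostic fixed-site discovery, ancestry painting and hybrid classification.

A *fixed (diagnostic) site* is one where every individual of one parental
panel is homozygous for one allele and every individual of the other panel
homozygous for the different allele. Over those sites a putative hybrid is
summarized by its *hybrid index* — the fraction of allele copies derived from
the species mapped to scale value 1 — and its *fixed-site heterozygosity*.
An F1 sits at (0.5, ≈1.0), a first-generation backcross near hybrid index
0.25 or 0.75, and later-generation hybrids show intermediate hybrid index
with reduced heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcfio import GenotypeMatrix

__all__ = [
    "FixedSiteSet",
    "HybridProfile",
    "ClassifierThresholds",
    "find_fixed_sites",
    "hybrid_profile",
    "classify",
    "profile_table",
    "painting_matrix",
]

LABELS = (
    "parental_like_0", "backcross_0", "later_generation", "F1_like",
    "backcross_1", "parental_like_1", "unclear",
)


@dataclass
class FixedSiteSet:
    """Sites fixed for alternative alleles between two parental panels.

    ``site_index`` indexes into the genotype matrix the set was derived
    from. ``species1_dosage`` gives, per fixed site, the dosage (0 or 2)
    carried by the species mapped to hybrid-index 1, which orients the
    scale: species 0 maps to hybrid index 0, species 1 to hybrid index 1.
    """

    site_index: np.ndarray
    species1_dosage: np.ndarray
    species0: str
    species1: str

    def __len__(self) -> int:
        return len(self.site_index)

    def flipped(self) -> "FixedSiteSet":
        """Same sites with the hybrid-index orientation reversed."""
        return FixedSiteSet(
            site_index=self.site_index,
            species1_dosage=2 - self.species1_dosage,
            species0=self.species1,
            species1=self.species0,
        )


@dataclass
class HybridProfile:
    """Per-individual ancestry-painting summary (one row of a Table-2-style table)."""

    sample: str
    hybrid_index: float
    heterozygosity: float
    n_sites_analyzed: int
    reliable: bool
    label: str | None = None
    maternal_species: str | None = None


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision bounds for hybrid classification.

    ``backcross_bound``: hybrid index ≤ b or ≥ 1−b ⇒ backcrossed toward that
    side. ``later_het_bound``: intermediate hybrid index with heterozygosity
    strictly below h ⇒ later-generation hybrid. F1 calls need the hybrid
    index within ``f1_delta`` of 0.5 and heterozygosity ≥ ``f1_het``. The
    parental band catches nonadmixed controls. Profiles are classified only
    when built from ≥ ``min_sites`` diagnostic sites.
    """

    backcross_bound: float = 0.25
    later_het_bound: float = 0.5
    f1_delta: float = 0.05
    f1_het: float = 0.9
    parental_band: float = 0.02
    min_completeness: float = 0.8
    min_sites: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.backcross_bound < 0.5:
            raise ValueError("backcross_bound must be in (0, 0.5)")
        if not 0.0 < self.later_het_bound <= 1.0:
            raise ValueError("later_het_bound must be in (0, 1]")


def find_fixed_sites(
    gm: GenotypeMatrix,
    panel0: list[str],
    panel1: list[str],
    allow_missing_fraction: float = 0.0,
    species0: str = "species0",
    species1: str = "species1",
) -> FixedSiteSet:
    """Find sites fixed for different alleles between two parental panels.

    A site qualifies iff, among non-missing genotypes, every panel-0
    individual is homozygous for one allele and every panel-1 individual
    homozygous for the other, with per-panel missingness at most
    ``allow_missing_fraction`` (default 0: every genotype present). The
    orientation maps ``panel0``'s species to hybrid index 0 and ``panel1``'s
    to 1.
    """
    if set(panel0) & set(panel1):
        raise ValueError(f"panels overlap: {sorted(set(panel0) & set(panel1))}")
    if not panel0 or not panel1:
        raise ValueError("both panels need at least one sample")

    def fixed_dosage(panel: list[str]) -> tuple[np.ndarray, np.ndarray]:
        d = gm.dosage[gm.sample_index(panel)]
        missing = d == -1
        ok_missing = missing.mean(axis=0) <= allow_missing_fraction
        any_called = (~missing).any(axis=0)
        hom0 = ((d == 0) | missing).all(axis=0)
        hom2 = ((d == 2) | missing).all(axis=0)
        value = np.where(hom2, 2, 0).astype(np.int8)
        return ok_missing & any_called & (hom0 | hom2), value

    ok0, val0 = fixed_dosage(panel0)
    ok1, val1 = fixed_dosage(panel1)
    fixed = ok0 & ok1 & (val0 != val1)
    idx = np.flatnonzero(fixed)
    return FixedSiteSet(site_index=idx, species1_dosage=val1[idx],
                        species0=species0, species1=species1)


def _analyzed_mask(gm: GenotypeMatrix, fixed: FixedSiteSet,
                   painted_samples: list[str] | None,
                   min_completeness: float) -> np.ndarray:
    """Fixed sites passing the completeness rule across the painted cohort."""
    painted = painted_samples if painted_samples is not None else list(gm.samples)
    d = gm.dosage[gm.sample_index(painted)][:, fixed.site_index]
    return (d != -1).mean(axis=0) >= min_completeness


def hybrid_profile(
    gm: GenotypeMatrix,
    fixed: FixedSiteSet,
    sample: str,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    painted_samples: list[str] | None = None,
    maternal_species: str | None = None,
) -> HybridProfile:
    """Hybrid index and fixed-site heterozygosity for one individual.

    A fixed site is analyzed for this individual when its own genotype is
    present and the site is genotyped in at least ``min_completeness`` of the
    painted cohort (all samples by default). The hybrid index counts allele
    copies of the species oriented to scale value 1 over 2 × analyzed sites.
    Profiles with fewer than ``min_sites`` analyzed sites are flagged
    unreliable and left unclassified.
    """
    complete = _analyzed_mask(gm, fixed, painted_samples, thresholds.min_completeness)
    d = gm.dosage[gm.sample_index(sample)[0], fixed.site_index]
    analyzed = complete & (d != -1)
    n = int(analyzed.sum())
    if n == 0:
        prof = HybridProfile(sample, np.nan, np.nan, 0, reliable=False,
                             maternal_species=maternal_species)
        return prof
    da = d[analyzed]
    # copies of the species-1 allele at each analyzed site
    sp1 = np.where(fixed.species1_dosage[analyzed] == 2, da, 2 - da)
    hi = float(sp1.sum() / (2 * n))
    het = float((da == 1).mean())
    reliable = n >= thresholds.min_sites
    prof = HybridProfile(sample, hi, het, n, reliable=reliable,
                         maternal_species=maternal_species)
    if reliable:
        prof.label = classify(prof, thresholds)
    return prof


def classify(profile: HybridProfile,
             thresholds: ClassifierThresholds = ClassifierThresholds()) -> str:
    """Assign a hybrid class from (hybrid index, heterozygosity).

    Rules, in order: F1-like for hybrid index within ``f1_delta`` of 0.5 and
    heterozygosity ≥ ``f1_het``; parental-like at the scale extremes with
    near-zero heterozygosity; backcross toward a side for hybrid index ≤ b
    or ≥ 1−b (inclusive bounds); later-generation for intermediate hybrid
    index (strict inequalities) with heterozygosity strictly below the
    later-generation bound; otherwise unclear (intermediate hybrid index but
    high heterozygosity).
    """
    t = thresholds
    hi, het = profile.hybrid_index, profile.heterozygosity
    if not np.isfinite(hi) or not np.isfinite(het):
        raise ValueError(f"cannot classify unreliable profile for {profile.sample}")
    if abs(hi - 0.5) <= t.f1_delta and het >= t.f1_het:
        return "F1_like"
    if hi <= t.parental_band and het <= t.parental_band:
        return "parental_like_0"
    if hi >= 1 - t.parental_band and het <= t.parental_band:
        return "parental_like_1"
    if hi <= t.backcross_bound:
        return "backcross_0"
    if hi >= 1 - t.backcross_bound:
        return "backcross_1"
    if het < t.later_het_bound:
        return "later_generation"
    return "unclear"


def profile_table(profiles: list[HybridProfile], fixed: FixedSiteSet) -> pd.DataFrame:
    """Table-2-style summary: one row per painted individual."""
    rows = [
        {
            "sample": p.sample,
            "hybrid_index": p.hybrid_index,
            "heterozygosity": p.heterozygosity,
            "n_sites": p.n_sites_analyzed,
            "maternal_species": p.maternal_species or "",
            "hybrid_pair": f"{fixed.species0}x{fixed.species1}",
            "interpretation": p.label if p.label else ("unreliable" if not p.reliable else ""),
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)


def painting_matrix(
    gm: GenotypeMatrix,
    fixed: FixedSiteSet,
    samples: list[str],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    painted_samples: list[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-sample per-site painting states over analyzed fixed sites.

    Returns ``(states, site_table)`` where states is int8 with 0 = homozygous
    species-0, 1 = heterozygous, 2 = homozygous species-1, −1 = missing —
    the plotting layout for ancestry paintings with scaffolds sorted by
    length. Row-wise state counts are consistent with ``hybrid_profile``.
    """
    complete = _analyzed_mask(gm, fixed, painted_samples, thresholds.min_completeness)
    idx = fixed.site_index[complete]
    d = gm.dosage[gm.sample_index(samples)][:, idx]
    sp1 = fixed.species1_dosage[complete]
    states = np.where(d == -1, -1, np.where(sp1 == 2, d, 2 - d)).astype(np.int8)
    site_table = gm.sites.iloc[idx].reset_index(drop=True)
    return states, site_table
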