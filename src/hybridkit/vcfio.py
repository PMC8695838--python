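"""VCF/GFF ingestion, cohort-level site filters, callability and allele balance.

Genotypes are held as an alt-allele dosage matrix (samples × sites, int8,
−1 for missing) with a pandas site table, the layout every downstream module
reads. Only biallelic SNPs survive ingestion; upstream caller-level filters
(GATK hard filters and the like) are assumed already applied to the VCF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GenotypeMatrix",
    "SiteFilterConfig",
    "read_vcf",
    "read_panel_table",
    "filter_sites",
    "genotyped_sites_per_window",
    "allele_balance",
    "read_gff_genes",
]

_SNP_ALLELES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Diploid genotype dosages with site metadata.

    ``dosage[i, j]`` is the alt-allele count (0/1/2) of sample ``i`` at site
    ``j``, −1 when missing. ``sites`` has columns scaffold, pos (1-based),
    ref, alt with positions strictly increasing within each scaffold.
    ``ad`` optionally carries per-genotype (ref, alt) read depths and
    ``site_depth`` the per-site total depth (INFO/DP when present).
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    ad: np.ndarray | None = None
    site_depth: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, names: list[str] | str) -> np.ndarray:
        if isinstance(names, str):
            names = [names]
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            ad=self.ad[:, idx] if self.ad is not None else None,
            site_depth=self.site_depth[idx] if self.site_depth is not None else None,
        )


@dataclass(frozen=True)
class SiteFilterConfig:
    """Cohort-level site exclusion thresholds.

    Sites with summed depth strictly above ``max_total_depth`` (a guard
    against collapsed repeats) or with a missing-genotype fraction strictly
    above ``max_missing_fraction`` are removed.
    """

    max_total_depth: int = 450
    max_missing_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")


def read_vcf(path: str, region: str | None = None) -> GenotypeMatrix:
    """Load biallelic SNP genotypes from a VCF (GT required, AD/DP kept).

    Multiallelic records and indels are excluded. ``region`` restricts to a
    samtools-style region string when the file is indexed.
    """
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare Exception on parse failure
        raise ValueError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains no samples")

    rows_scaffold, rows_pos, rows_ref, rows_alt = [], [], [], []
    dosages, ads, depths = [], [], []
    any_ad = False
    any_dp = False
    it = vcf(region) if region else vcf
    for v in it:
        if len(v.ALT) != 1:
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = v.gt_types.astype(np.int8)
        gt[gt == 3] = -1
        dosages.append(gt)
        rows_scaffold.append(v.CHROM)
        rows_pos.append(v.POS)
        rows_ref.append(ref)
        rows_alt.append(alt)
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            ads.append(np.clip(ad[:, :2], 0, None).astype(np.int32))
            any_ad = True
        else:
            ads.append(np.zeros((len(samples), 2), dtype=np.int32))
        dp = v.INFO.get("DP")
        depths.append(-1 if dp is None else int(dp))
        if dp is not None:
            any_dp = True
    vcf.close()

    sites = pd.DataFrame({"scaffold": rows_scaffold, "pos": rows_pos,
                          "ref": rows_ref, "alt": rows_alt})
    dosage = (np.array(dosages, dtype=np.int8).T if dosages
              else np.zeros((len(samples), 0), dtype=np.int8))
    gm = GenotypeMatrix(
        samples=samples,
        sites=sites,
        dosage=dosage,
        ad=np.stack(ads).transpose(1, 0, 2) if any_ad else None,
        site_depth=np.array(depths) if any_dp else None,
    )
    _check_sorted(gm.sites)
    return gm


def _check_sorted(sites: pd.DataFrame) -> None:
    for scaf, grp in sites.groupby("scaffold", sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValueError(f"positions not strictly increasing on {scaf}")


def read_panel_table(path: str) -> dict[str, str]:
    """Read a sample→species assignment TSV (columns: sample, species)."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "species" not in df.columns:
        raise ValueError(f"panel table {path} needs 'sample' and 'species' columns")
    return dict(zip(df["sample"].astype(str), df["species"].astype(str)))


def filter_sites(gm: GenotypeMatrix, cfg: SiteFilterConfig = SiteFilterConfig()) -> GenotypeMatrix:
    """Drop sites over the depth cap or the missingness cap (strict >).

    Total depth is the site-level DP when present, else the summed AD over
    samples; sites lacking both are not depth-filtered. Idempotent.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    if gm.site_depth is not None:
        known = gm.site_depth >= 0
        keep &= ~(known & (gm.site_depth > cfg.max_total_depth))
    elif gm.ad is not None:
        total = gm.ad.sum(axis=(0, 2))
        keep &= total <= cfg.max_total_depth
    if gm.n_samples:
        miss_frac = (gm.dosage == -1).mean(axis=0)
        keep &= miss_frac <= cfg.max_missing_fraction
    return gm.take_sites(keep)


def genotyped_sites_per_window(
    source,
    windows: pd.DataFrame,
    min_called_fraction: float = 0.8,
) -> np.ndarray:
    """Count genotyped (variant + invariant) sites in each window.

    ``source`` is either a mapping scaffold → sorted array of genotyped
    positions (e.g. from an all-sites caller or a callability mask), or a
    path to an all-sites VCF, in which case a position counts as genotyped
    when at least ``min_called_fraction`` of genotypes are non-missing.
    ``windows`` needs scaffold/start/end columns (1-based inclusive).
    """
    if source is None:
        raise ValueError(
            "window statistics need a genotyped-site source: pass a per-scaffold "
            "position mapping or an all-sites VCF path")
    if isinstance(source, (str, bytes)):
        positions: dict[str, np.ndarray] = {}
        vcf = VCF(source, gts012=True)
        for v in vcf:
            gt = v.gt_types
            if (gt != 3).mean() >= min_called_fraction:
                positions.setdefault(v.CHROM, []).append(v.POS)
        vcf.close()
        positions = {k: np.asarray(v) for k, v in positions.items()}
    else:
        positions = {k: np.asarray(v) for k, v in source.items()}

    counts = np.zeros(len(windows), dtype=np.int64)
    for i, (scaf, start, end) in enumerate(
            zip(windows["scaffold"], windows["start"], windows["end"])):
        pos = positions.get(scaf)
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, end, "right") - np.searchsorted(pos, start, "left")
    return counts


def allele_balance(gm: GenotypeMatrix, samples: list[str] | None = None) -> pd.DataFrame:
    """Reference-read fraction at heterozygous genotypes, per sample.

    The reference-bias check: without mapping bias the reference allele
    carries about half the reads at heterozygous genotypes, so per-sample
    medians near 0.5 are the unbiased expectation. Returns a DataFrame with
    median/q25/q75/n_het per sample; samples with no usable heterozygous
    genotype get NaN summaries and ``assessable = False``.
    """
    if gm.ad is None:
        raise ValueError("allele balance needs AD (per-genotype allele depths)")
    samples = samples if samples is not None else list(gm.samples)
    idx = gm.sample_index(samples)
    out = []
    for name, i in zip(samples, idx):
        het = gm.dosage[i] == 1
        ad = gm.ad[i, het]
        tot = ad.sum(axis=1)
        frac = ad[tot > 0, 0] / tot[tot > 0]
        if frac.size == 0:
            out.append((name, np.nan, np.nan, np.nan, 0, False))
        else:
            q25, med, q75 = np.percentile(frac, [25, 50, 75])
            out.append((name, med, q25, q75, int(frac.size), True))
    return pd.DataFrame(out, columns=["sample", "median_ref_fraction", "q25", "q75",
                                      "n_het", "assessable"])


def read_gff_genes(path: str) -> pd.DataFrame:
    """Extract gene intervals (scaffold, start, end, gene_id) from a GFF3.

    Coordinates are 1-based inclusive as in the file. Malformed lines are
    skipped; the count of skipped lines is attached as ``df.attrs['n_skipped']``.
    """
    rows = []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                n_skipped += 1
                continue
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                n_skipped += 1
                continue
            gene_id = None
            for attr in parts[8].split(";"):
                if attr.startswith("ID="):
                    gene_id = attr[3:]
                    break
            rows.append((parts[0], start, end, gene_id or f"gene_{len(rows) + 1}"))
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end", "gene_id"])
    df.attrs["n_skipped"] = n_skipped
    return df
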