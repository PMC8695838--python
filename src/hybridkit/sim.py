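"""Hybrid-pedigree simulator with known ancestry truth.

Generates diverged parental species panels and admixed individuals (F1,
backcrosses, later-generation hybrids) on a scaffold-structured genome with
recombination, so that every downstream analysis — diagnostic-site discovery,
ancestry painting, window statistics, f3 tests, tract extraction — can be
validated against known truth without any external data.

The divergence model is Balding–Nichols: each species' allele frequency at a
site is a Beta draw around a shared ancestral frequency, with a single
parameter ``F`` controlling the FST-scale differentiation between species.
Diagnostic sites are modelled as frequency-(0, 1) sites between the focal
species pair, so F1 expectations (hybrid index 0.5, heterozygosity 1.0) hold
exactly. Recombination is a Poisson crossover process without interference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "SpeciesFrequencies",
    "PedigreeSpec",
    "TruthRecord",
    "SimulatedDataset",
    "default_layout",
    "build_species_frequencies",
    "drift_frequencies",
    "sample_parental_genotypes",
    "pure_mosaic",
    "meiosis",
    "realize_pedigree",
    "genotypes_from_mosaic",
    "simulate_allele_depths",
    "simulate_dataset",
    "emit_dataset",
]

# A haplotype mosaic is a mapping scaffold name -> list of (start, end, label)
# segments, 1-based inclusive, tiling [1, scaffold length] with no gaps or
# overlaps and no two adjacent segments sharing a label.
Mosaic = dict[str, list[tuple[int, int, str]]]


@dataclass(frozen=True)
class GenomeLayout:
    """Scaffold structure and crossover density of the simulated genome.

    Parameters
    ----------
    scaffolds
        Ordered ``(name, length_bp)`` pairs. Names must be unique and
        lengths at least 1 bp.
    morgans_per_bp
        Crossover density; the expected crossover count per meiosis on a
        scaffold of length ``L`` is ``L * morgans_per_bp``.
    """

    scaffolds: tuple[tuple[str, int], ...]
    morgans_per_bp: float = 1e-8

    def __post_init__(self) -> None:
        names = [n for n, _ in self.scaffolds]
        if len(set(names)) != len(names):
            raise ValueError("scaffold names must be unique")
        if any(length < 1 for _, length in self.scaffolds):
            raise ValueError("scaffold lengths must be >= 1 bp")
        if self.morgans_per_bp < 0:
            raise ValueError("morgans_per_bp must be non-negative")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.scaffolds]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.scaffolds)

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.scaffolds)


def default_layout(n_scaffolds: int = 10, scaffold_bp: int = 1_000_000,
                   morgans_per_bp: float = 1e-8) -> GenomeLayout:
    """Ten 1-Mb scaffolds at a human-scale crossover density, overridable."""
    return GenomeLayout(
        scaffolds=tuple((f"scaffold_{i + 1}", scaffold_bp) for i in range(n_scaffolds)),
        morgans_per_bp=morgans_per_bp,
    )


@dataclass
class SpeciesFrequencies:
    """Per-species alt-allele frequencies at simulated SNP sites.

    ``sites`` holds scaffold and 1-based position (sorted); ``freqs`` maps a
    species label to its per-site alt-allele frequency; ``diagnostic`` marks
    sites fixed for alternative alleles between the focal pair; ``focal_pair``
    names the two species the diagnostic sites separate.
    """

    sites: pd.DataFrame
    ancestral: np.ndarray
    freqs: dict[str, np.ndarray]
    diagnostic: np.ndarray
    focal_pair: tuple[str, str]
    fst: float

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def species(self) -> list[str]:
        return list(self.freqs)


@dataclass(frozen=True)
class PedigreeSpec:
    """Recipe for one admixed (or parental) individual.

    ``kind`` is one of ``parental``, ``F1``, ``BC1``, ``BCn`` (``n`` repeated
    backcrosses) or ``later_generation`` (``g`` sexual generations of mating
    in a closed hybrid swarm seeded by F1s). ``backcross_to`` selects the
    recurrent parental species for backcrosses; ``species`` picks the single
    species of a parental individual.
    """

    kind: str
    pair: tuple[str, str] = ("A", "B")
    species: str | None = None
    backcross_to: str | None = None
    n: int = 1
    g: int = 1

    def __post_init__(self) -> None:
        kinds = {"parental", "F1", "BC1", "BCn", "later_generation"}
        if self.kind not in kinds:
            raise ValueError(f"unknown pedigree kind {self.kind!r}; expected one of {sorted(kinds)}")
        if self.kind == "parental" and self.species not in self.pair:
            raise ValueError("parental spec needs species set to one of the pair")
        if self.kind in ("BC1", "BCn") and self.backcross_to not in self.pair:
            raise ValueError("backcross spec needs backcross_to set to one of the pair")
        if self.kind == "BCn" and self.n < 1:
            raise ValueError("BCn needs n >= 1")
        if self.kind == "later_generation" and self.g < 1:
            raise ValueError("later_generation needs g >= 1")


@dataclass
class TruthRecord:
    """Known ancestry truth for one simulated individual."""

    sample: str
    pedigree: str
    prop_a: float  # fraction of bp (over both haplotypes) with first-species ancestry
    breakpoints: int  # within-haplotype ancestry switches, summed over haplotypes

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_a <= 1.0:
            raise ValueError("ancestry proportion must be in [0, 1]")
        if self.breakpoints < 0:
            raise ValueError("breakpoint count must be >= 0")


# ---------------------------------------------------------------------------
# frequencies and genotypes

def _uniform_positions(layout: GenomeLayout, n_sites: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n_sites unique positions uniformly over the genome, sorted."""
    lengths = np.array([length for _, length in layout.scaffolds], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = offsets[-1]
    if n_sites > total:
        raise ValueError(f"cannot place {n_sites} unique sites on a {total}-bp genome")
    # rejection-free unique draw: sample extra and deduplicate
    flat = rng.choice(total, size=n_sites, replace=False)
    flat.sort()
    scaf_idx = np.searchsorted(offsets, flat, side="right") - 1
    pos = flat - offsets[scaf_idx] + 1  # 1-based
    names = np.array(layout.names)
    return pd.DataFrame({"scaffold": names[scaf_idx], "pos": pos.astype(np.int64)})


def drift_frequencies(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F) around ``p``.

    ``f`` is the divergence parameter in [0, 1); ``f = 0`` returns ``p``
    unchanged (the zero-variance limit). Frequencies exactly 0 or 1 are
    passed through (the Beta is degenerate there).
    """
    if not 0.0 <= f < 1.0:
        raise ValueError(f"divergence parameter must be in [0, 1), got {f}")
    p = np.asarray(p, dtype=float)
    if f == 0.0:
        return p.copy()
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    scale = (1.0 - f) / f
    out[interior] = rng.beta(p[interior] * scale, (1.0 - p[interior]) * scale)
    return out


def build_species_frequencies(
    layout: GenomeLayout,
    n_sites: int,
    fst: float,
    prop_diagnostic: float,
    seed: int | np.random.Generator,
    species: tuple[str, ...] = ("A", "B"),
    focal_pair: tuple[str, str] | None = None,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
) -> SpeciesFrequencies:
    """Draw per-species allele frequencies under Balding–Nichols divergence.

    A fraction ``prop_diagnostic`` of sites is made diagnostic for the focal
    pair: frequency 0 in one focal species and 1 in the other (orientation
    random per site). All other sites get independent Beta draws per species
    around a shared ancestral frequency drawn uniformly from
    ``ancestral_range``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0.0 <= prop_diagnostic <= 1.0:
        raise ValueError("prop_diagnostic must be in [0, 1]")
    if not 0.0 <= fst < 1.0:
        raise ValueError(f"divergence parameter must be in [0, 1), got {fst}")
    if focal_pair is None:
        focal_pair = (species[0], species[1])
    if focal_pair[0] not in species or focal_pair[1] not in species:
        raise ValueError("focal_pair must name two of the species")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sites = _uniform_positions(layout, n_sites, rng)
    lo, hi = ancestral_range
    ancestral = rng.uniform(lo, hi, size=n_sites)

    n_diag = int(round(prop_diagnostic * n_sites))
    diagnostic = np.zeros(n_sites, dtype=bool)
    if n_diag:
        diagnostic[rng.choice(n_sites, size=n_diag, replace=False)] = True

    freqs = {sp: drift_frequencies(ancestral, fst, rng) for sp in species}
    # orientation: which focal species carries the alt allele at each diagnostic site
    alt_in_first = rng.random(n_sites) < 0.5
    a, b = focal_pair
    freqs[a][diagnostic] = np.where(alt_in_first[diagnostic], 1.0, 0.0)
    freqs[b][diagnostic] = np.where(alt_in_first[diagnostic], 0.0, 1.0)
    return SpeciesFrequencies(
        sites=sites, ancestral=ancestral, freqs=freqs,
        diagnostic=diagnostic, focal_pair=focal_pair, fst=fst,
    )


def sample_parental_genotypes(
    freqs: SpeciesFrequencies,
    species: str,
    n_individuals: int,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Binomial(2, p) genotype dosages for a panel of one species.

    Returns an ``(n_individuals, n_sites)`` int8 array of alt-allele dosages
    with ``-1`` marking missing genotypes injected at ``missing_rate``.
    """
    if species not in freqs.freqs:
        raise KeyError(f"unknown species label {species!r}; have {freqs.species}")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = freqs.freqs[species]
    dosage = rng.binomial(2, p, size=(n_individuals, freqs.n_sites)).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = -1
    return dosage


# ---------------------------------------------------------------------------
# mosaics and meiosis

def pure_mosaic(layout: GenomeLayout, label: str) -> Mosaic:
    """Whole-genome single-ancestry haplotype."""
    return {name: [(1, length, label)] for name, length in layout.scaffolds}


def _merge_segments(segs: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    merged: list[tuple[int, int, str]] = []
    for s, e, lab in segs:
        if merged and merged[-1][2] == lab and merged[-1][1] + 1 == s:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return merged


def _slice_segments(segs: list[tuple[int, int, str]], lo: int, hi: int) -> list[tuple[int, int, str]]:
    """Clip a tiling segment list to [lo, hi] inclusive."""
    out = []
    for s, e, lab in segs:
        if e < lo or s > hi:
            continue
        out.append((max(s, lo), min(e, hi), lab))
    return out


def validate_mosaic(mosaic: Mosaic, layout: GenomeLayout) -> None:
    """Assert the mosaic tiles every scaffold with alternating labels."""
    lengths = layout.lengths
    if set(mosaic) != set(lengths):
        raise ValueError("mosaic scaffolds do not match layout")
    for name, segs in mosaic.items():
        if segs[0][0] != 1 or segs[-1][1] != lengths[name]:
            raise ValueError(f"{name}: segments do not span [1, {lengths[name]}]")
        for (s1, e1, l1), (s2, e2, l2) in zip(segs, segs[1:]):
            if s2 != e1 + 1:
                raise ValueError(f"{name}: gap or overlap at {e1}/{s2}")
            if l1 == l2:
                raise ValueError(f"{name}: adjacent segments share label {l1}")


def meiosis(parent: tuple[Mosaic, Mosaic], layout: GenomeLayout,
            seed: int | np.random.Generator = 0) -> Mosaic:
    """One gamete from a diploid parent under Poisson recombination.

    Per scaffold, the crossover count is Poisson(length × morgans_per_bp)
    with breakpoints uniform along the scaffold; the gamete starts on a
    fair-coin haplotype and alternates at each breakpoint.
    """
    hap0, hap1 = parent
    if set(hap0) != set(hap1) or set(hap0) != set(layout.lengths):
        raise ValueError("parent haplotypes and layout cover different scaffolds")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gamete: Mosaic = {}
    for name, length in layout.scaffolds:
        n_xo = rng.poisson(length * layout.morgans_per_bp)
        # a breakpoint at position b switches the template from b onward
        bps = np.unique(rng.integers(2, length + 1, size=n_xo)) if n_xo else np.array([], dtype=int)
        bounds = [1, *bps.tolist(), length + 1]
        current = int(rng.integers(2))
        segs: list[tuple[int, int, str]] = []
        haps = (hap0[name], hap1[name])
        for lo, hi in zip(bounds, bounds[1:]):
            segs.extend(_slice_segments(haps[current], lo, hi - 1))
            current ^= 1
        gamete[name] = _merge_segments(segs)
    return gamete


def _truth_from_mosaics(sample: str, pedigree: str, mosaics: tuple[Mosaic, Mosaic],
                        layout: GenomeLayout, label_a: str) -> TruthRecord:
    total = 2 * layout.total_bp
    bp_a = 0
    breakpoints = 0
    for hap in mosaics:
        for segs in hap.values():
            bp_a += sum(e - s + 1 for s, e, lab in segs if lab == label_a)
            breakpoints += len(segs) - 1
    return TruthRecord(sample=sample, pedigree=pedigree,
                       prop_a=bp_a / total, breakpoints=breakpoints)


def realize_pedigree(
    spec: PedigreeSpec,
    layout: GenomeLayout,
    seed: int | np.random.Generator = 0,
    sample: str = "ind",
) -> tuple[tuple[Mosaic, Mosaic], TruthRecord]:
    """Simulate one individual's ancestry mosaic from a pedigree recipe.

    F1 carries one pure haplotype from each focal species. BC1 is an F1
    gamete plus a pure haplotype of the recurrent species; BCn repeats the
    backcross n times. ``later_generation`` seeds a small closed swarm with
    F1s and mates random (hybrid) members for g−1 further generations, so g
    counts sexual generations since the parental cross.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a, b = spec.pair
    pure = {a: pure_mosaic(layout, a), b: pure_mosaic(layout, b)}

    if spec.kind == "parental":
        mosaics = (pure[spec.species], pure[spec.species])
    elif spec.kind == "F1":
        mosaics = (pure[a], pure[b])
    elif spec.kind in ("BC1", "BCn"):
        n_rounds = 1 if spec.kind == "BC1" else spec.n
        child: tuple[Mosaic, Mosaic] = (pure[a], pure[b])  # F1
        for _ in range(n_rounds):
            child = (meiosis(child, layout, rng), pure[spec.backcross_to])
        mosaics = child
    else:  # later_generation
        swarm_size = 4
        swarm = [(pure[a], pure[b]) for _ in range(swarm_size)]  # generation 1: F1s
        for _ in range(spec.g - 1):
            nxt = []
            for _ in range(swarm_size):
                i, j = rng.choice(len(swarm), size=2, replace=False)
                nxt.append((meiosis(swarm[i], layout, rng), meiosis(swarm[j], layout, rng)))
            swarm = nxt
        mosaics = swarm[int(rng.integers(len(swarm)))]

    truth = _truth_from_mosaics(sample, spec.kind, mosaics, layout, label_a=a)
    return mosaics, truth


# ---------------------------------------------------------------------------
# genotypes from mosaics

def _site_labels(mosaic: Mosaic, sites: pd.DataFrame) -> np.ndarray:
    """Ancestry label of each site on one haplotype."""
    labels = np.empty(len(sites), dtype=object)
    for name, grp in sites.groupby("scaffold", sort=False):
        if name not in mosaic:
            raise ValueError(f"site scaffold {name!r} not covered by the mosaic")
        segs = mosaic[name]
        starts = np.array([s for s, _, _ in segs])
        ends = np.array([e for _, e, _ in segs])
        labs = np.array([lab for _, _, lab in segs], dtype=object)
        pos = grp["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        if (idx < 0).any() or (pos > ends[idx]).any():
            raise ValueError(f"site position outside mosaic segments on {name}")
        labels[grp.index.to_numpy()] = labs[idx]
    return labels


def genotypes_from_mosaic(
    mosaics: tuple[Mosaic, Mosaic],
    freqs: SpeciesFrequencies,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one individual's genotype row from its ancestry mosaic.

    Each haplotype's allele at a site is Bernoulli(alt frequency of the
    segment's ancestry species); returns ``(dosage, haplotype_alleles)``
    where ``dosage`` is int8 of length n_sites and ``haplotype_alleles`` is
    an (2, n_sites) 0/1 array.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hap_alleles = np.empty((2, freqs.n_sites), dtype=np.int8)
    for h, mosaic in enumerate(mosaics):
        labels = _site_labels(mosaic, freqs.sites)
        p = np.empty(freqs.n_sites)
        for sp in freqs.species:
            mask = labels == sp
            p[mask] = freqs.freqs[sp][mask]
        hap_alleles[h] = rng.random(freqs.n_sites) < p
    return (hap_alleles[0] + hap_alleles[1]).astype(np.int8), hap_alleles


def simulate_allele_depths(
    dosage: np.ndarray,
    mean_depth: float = 30.0,
    ref_bias: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate (ref, alt) read depths for a dosage array of any shape.

    Total depth is Poisson(mean_depth); at heterozygous genotypes reference
    reads are Binomial(depth, ref_bias); homozygous genotypes put all reads
    on the carried allele. Missing genotypes get zero depth. Returns an
    array of shape ``dosage.shape + (2,)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dosage = np.asarray(dosage)
    depth = rng.poisson(mean_depth, size=dosage.shape)
    ref = np.where(dosage == 0, depth, 0)
    het = dosage == 1
    ref = ref + np.where(het, rng.binomial(depth, ref_bias), 0)
    ad = np.stack([ref, depth - ref], axis=-1).astype(np.int32)
    ad[dosage == -1] = 0
    return ad


# ---------------------------------------------------------------------------
# dataset assembly and text output

@dataclass
class SimulatedDataset:
    """In-memory simulated cohort: panels plus pedigreed hybrids."""

    layout: GenomeLayout
    freqs: SpeciesFrequencies
    samples: list[str]
    species_of: dict[str, str]  # sample -> species label or "admixed"
    dosage: np.ndarray  # (n_samples, n_sites) int8, -1 missing
    ad: np.ndarray | None  # (n_samples, n_sites, 2) or None
    truth: list[TruthRecord]
    hap_ancestry: dict[str, np.ndarray]  # sample -> (2, n_sites) object array of labels
    mosaics: dict[str, tuple[Mosaic, Mosaic]] = field(default_factory=dict)

    @property
    def panels(self) -> dict[str, list[str]]:
        """Sample ids grouped by species label (admixed under 'admixed')."""
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(self.species_of[s], []).append(s)
        return out


def simulate_dataset(
    layout: GenomeLayout,
    freqs: SpeciesFrequencies,
    panel_sizes: dict[str, int],
    pedigrees: list[tuple[str, PedigreeSpec]],
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
    with_depth: bool = False,
    mean_depth: float = 30.0,
) -> SimulatedDataset:
    """Simulate parental panels and pedigreed hybrids into one cohort.

    ``panel_sizes`` maps species label -> number of parental individuals;
    ``pedigrees`` is a list of (sample id, PedigreeSpec) for admixed (or
    extra parental) individuals whose ancestry mosaics are tracked as truth.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples: list[str] = []
    species_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    truth: list[TruthRecord] = []
    hap_anc: dict[str, np.ndarray] = {}
    mosaics: dict[str, tuple[Mosaic, Mosaic]] = {}

    for sp, size in panel_sizes.items():
        panel = sample_parental_genotypes(freqs, sp, size, missing_rate, rng)
        for i in range(size):
            sid = f"{sp}_{i + 1}"
            samples.append(sid)
            species_of[sid] = sp
            rows.append(panel[i])

    for sid, spec in pedigrees:
        pair_mosaics, rec = realize_pedigree(spec, layout, rng, sample=sid)
        dosage, haps = genotypes_from_mosaic(pair_mosaics, freqs, rng)
        if missing_rate > 0:
            dosage = dosage.copy()
            dosage[rng.random(dosage.shape) < missing_rate] = -1
        samples.append(sid)
        species_of[sid] = spec.species if spec.kind == "parental" else "admixed"
        rows.append(dosage)
        truth.append(rec)
        labels = np.empty((2, freqs.n_sites), dtype=object)
        for h in range(2):
            labels[h] = _site_labels(pair_mosaics[h], freqs.sites)
        hap_anc[sid] = labels
        mosaics[sid] = pair_mosaics

    dosage_mat = np.vstack(rows)
    ad = simulate_allele_depths(dosage_mat, mean_depth, 0.5, rng) if with_depth else None
    return SimulatedDataset(
        layout=layout, freqs=freqs, samples=samples, species_of=species_of,
        dosage=dosage_mat, ad=ad, truth=truth, hap_ancestry=hap_anc, mosaics=mosaics,
    )


_BASES = np.array(list("ACGT"))


def emit_dataset(ds: SimulatedDataset, out_prefix: str,
                 seed: int | np.random.Generator = 0) -> dict[str, str]:
    """Write a simulated cohort as VCF + panel table + truth + ancestry TSVs.

    Emits ``<prefix>.vcf`` (VCF 4.2 with GT, and AD when simulated),
    ``<prefix>.panels.tsv`` (sample, species), ``<prefix>.truth.tsv`` and
    ``<prefix>.ancestry.tsv`` (per-haplotype ancestry labels of the
    pedigreed individuals, sites × haplotypes). Returns the path map.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_sites = ds.freqs.n_sites
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref, alt = _BASES[ref_idx], _BASES[alt_idx]

    paths = {
        "vcf": f"{out_prefix}.vcf",
        "panels": f"{out_prefix}.panels.tsv",
        "truth": f"{out_prefix}.truth.tsv",
        "ancestry": f"{out_prefix}.ancestry.tsv",
    }
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with_ad = ds.ad is not None
    try:
        with open(paths["vcf"], "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name, length in ds.layout.scaffolds:
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            if with_ad:
                fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                         'Description="Allelic depths (ref,alt)">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(ds.samples) + "\n")
            fmt = "GT:AD" if with_ad else "GT"
            scafs = ds.freqs.sites["scaffold"].to_numpy()
            poss = ds.freqs.sites["pos"].to_numpy()
            for j in range(n_sites):
                cells = []
                for i in range(len(ds.samples)):
                    gt = gt_map[int(ds.dosage[i, j])]
                    if with_ad:
                        gt = f"{gt}:{ds.ad[i, j, 0]},{ds.ad[i, j, 1]}"
                    cells.append(gt)
                fh.write(f"{scafs[j]}\t{poss[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\t{fmt}\t"
                         + "\t".join(cells) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing VCF to {paths['vcf']}: {exc}") from exc

    pd.DataFrame({"sample": ds.samples,
                  "species": [ds.species_of[s] for s in ds.samples]},
                 ).to_csv(paths["panels"], sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(t) for t in ds.truth]).rename(
        columns={"pedigree": "class", "prop_a": "true_prop_A"},
    ).to_csv(paths["truth"], sep="\t", index=False)

    anc = ds.freqs.sites.copy()
    for sid, labels in ds.hap_ancestry.items():
        anc[f"{sid}_h1"] = labels[0]
        anc[f"{sid}_h2"] = labels[1]
    anc.to_csv(paths["ancestry"], sep="\t", index=False)
    return paths
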