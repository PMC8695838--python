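"""Per-SNP ancestry states, tract extraction and genome-wide summaries.

Consumes diploid ancestry states from the naive diagnostic painting, phased
per-haplotype states from an external local-ancestry tool's matrix, or the
simulator's truth, and converts them to *ancestry tracts*: maximal runs of
identical non-missing state within one scaffold. A tract ends where the
state of a SNP changes to the other species or at the end of a scaffold;
summaries report ancestry proportion, ancestry heterozygosity, transition
counts and the tract-length distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AncestryStates",
    "TractSet",
    "naive_paint",
    "states_from_truth",
    "read_haplotype_ancestry",
    "extract_tracts",
    "summarize_ancestry",
    "tract_length_histogram",
]

# diploid states: 0 = AA, 1 = AB, 2 = BB, -1 = missing
# haplotype states: 0 = A, 1 = B, -1 = missing
DIPLOID_LABELS = {0: "AA", 1: "AB", 2: "BB"}
HAPLOID_LABELS = {0: "A", 1: "B"}


@dataclass
class AncestryStates:
    """Ordered per-SNP ancestry states for a set of sequences.

    ``kind`` is ``'diploid'`` (one unphased state per individual) or
    ``'haplotype'`` (one binary state per phased haplotype); the two are
    never mixed in one container. ``sites`` carries (scaffold, pos) with
    positions strictly increasing within scaffolds; ``states`` maps a
    sequence id to an int8 array over sites.
    """

    kind: str
    sites: pd.DataFrame
    states: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("diploid", "haplotype"):
            raise ValueError("kind must be 'diploid' or 'haplotype'")
        for scaf, grp in self.sites.groupby("scaffold", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {scaf}")
        n = len(self.sites)
        for sid, arr in self.states.items():
            if arr.shape != (n,):
                raise ValueError(f"state vector of {sid!r} does not match site count")

    @property
    def labels(self) -> dict[int, str]:
        return DIPLOID_LABELS if self.kind == "diploid" else HAPLOID_LABELS


@dataclass
class TractSet:
    """Extracted ancestry tracts plus the site table they came from."""

    tracts: pd.DataFrame  # id, scaffold, start, end, bp, n_snps, state
    sites: pd.DataFrame
    kind: str


def naive_paint(gm, fixed, sample: str) -> AncestryStates:
    """Diploid ancestry states of one individual at diagnostic fixed sites.

    AA = homozygous for the species-0 allele, BB = homozygous species-1,
    AB = heterozygous, missing otherwise — the unphased painting encoding.
    """
    d = gm.dosage[gm.sample_index(sample)[0], fixed.site_index]
    state = np.where(d == -1, -1, np.where(fixed.species1_dosage == 2, d, 2 - d))
    sites = gm.sites.iloc[fixed.site_index][["scaffold", "pos"]].reset_index(drop=True)
    return AncestryStates(kind="diploid", sites=sites,
                          states={sample: state.astype(np.int8)})


def states_from_truth(ds, samples: list[str] | None = None) -> AncestryStates:
    """Phased haplotype states from the simulator's true ancestry labels."""
    samples = samples if samples is not None else list(ds.hap_ancestry)
    a, b = ds.freqs.focal_pair
    states = {}
    for sid in samples:
        labels = ds.hap_ancestry[sid]
        for h in range(2):
            states[f"{sid}_h{h + 1}"] = np.where(labels[h] == b, 1, 0).astype(np.int8)
    sites = ds.freqs.sites[["scaffold", "pos"]].reset_index(drop=True)
    return AncestryStates(kind="haplotype", sites=sites, states=states)


def read_haplotype_ancestry(path: str, labels: tuple[str, str] = ("A", "B")) -> AncestryStates:
    """Read a phased per-haplotype ancestry matrix (sites × haplotypes TSV).

    The first two columns are scaffold and position; every further column is
    one haplotype with values in {A, B} (or {0, 1}). Rows must be sorted by
    position within scaffolds and values strictly binary.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need scaffold, pos and at least one haplotype column")
    sites = df.iloc[:, :2].copy()
    sites.columns = ["scaffold", "pos"]
    states = {}
    allowed = {labels[0]: 0, labels[1]: 1, "0": 0, "1": 1, 0: 0, 1: 1}
    for col in df.columns[2:]:
        mapped = df[col].map(allowed)
        if mapped.isna().any():
            bad = sorted(set(df[col][mapped.isna()].astype(str)))
            raise ValueError(f"{path}: column {col!r} has non-binary ancestry values {bad}")
        states[col] = mapped.to_numpy(dtype=np.int8)
    try:
        return AncestryStates(kind="haplotype", sites=sites, states=states)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def extract_tracts(states: AncestryStates, bridge_missing: bool = True) -> TractSet:
    """Split state sequences into maximal constant-ancestry tracts.

    A new tract starts when the state changes or a scaffold ends. Missing
    states bridge runs by default (they never start or end a tract);
    ``bridge_missing=False`` makes them break runs instead. Tract bp length
    is last − first SNP position + 1, so a single-SNP tract has length 1.
    """
    if not states.states:
        raise ValueError("no state sequences to extract tracts from")
    labels = states.labels
    rows = []
    scafs = states.sites["scaffold"].to_numpy()
    poss = states.sites["pos"].to_numpy()
    # scaffolds in order of first appearance
    order = pd.unique(scafs)
    for sid, arr in states.states.items():
        for scaf in order:
            m = scafs == scaf
            st, pp = arr[m], poss[m]
            keep = st != -1
            st, pp = st[keep], pp[keep]
            if st.size == 0:
                continue
            if bridge_missing:
                change = np.flatnonzero(np.diff(st) != 0) + 1
            else:
                # missing already dropped; break where sites were skipped
                idx_all = np.flatnonzero(keep)
                gap = np.diff(idx_all) > 1
                change = np.flatnonzero((np.diff(st) != 0) | gap) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [st.size]]) - 1
            for s, e in zip(starts, ends):
                rows.append((sid, scaf, int(pp[s]), int(pp[e]),
                             int(pp[e] - pp[s] + 1), int(e - s + 1),
                             labels[int(st[s])]))
    tracts = pd.DataFrame(rows, columns=["id", "scaffold", "start", "end",
                                         "bp", "n_snps", "state"])
    return TractSet(tracts=tracts, sites=states.sites, kind=states.kind)


def summarize_ancestry(tracts: TractSet, states: AncestryStates) -> pd.DataFrame:
    """Genome-wide per-sequence summary of ancestry composition.

    Reports the ancestry proportion of species B (allele-copy fraction for
    diploid states, state fraction for haplotypes), ancestry heterozygosity
    (fraction of SNPs in state AB; haplotype sequences report 0), the number
    of ancestry transitions — tracts minus scaffolds with data, i.e. only
    within-scaffold switches count — and the tract-length distribution.
    """
    out = []
    for sid, arr in states.states.items():
        called = arr != -1
        n = int(called.sum())
        sub = tracts.tracts[tracts.tracts["id"] == sid]
        n_scaf = sub["scaffold"].nunique()
        transitions = len(sub) - n_scaf
        if states.kind == "diploid":
            prop_b = float(arr[called].sum() / (2 * n)) if n else np.nan
            het = float((arr[called] == 1).mean()) if n else np.nan
        else:
            prop_b = float(arr[called].mean()) if n else np.nan
            het = 0.0
        out.append({
            "id": sid,
            "n_snps": n,
            "prop_B": prop_b,
            "prop_A": 1 - prop_b if n else np.nan,
            "ancestry_heterozygosity": het,
            "n_tracts": len(sub),
            "n_transitions": int(transitions),
            "mean_tract_bp": float(sub["bp"].mean()) if len(sub) else np.nan,
            "max_tract_bp": int(sub["bp"].max()) if len(sub) else 0,
        })
    return pd.DataFrame(out)


def tract_length_histogram(tracts: TractSet, bins: int | np.ndarray = 30,
                           log_scale: bool = True) -> pd.DataFrame:
    """Histogram of tract bp lengths per sequence id (plotting payload)."""
    rows = []
    lengths_all = tracts.tracts["bp"].to_numpy()
    if isinstance(bins, int):
        lo, hi = max(lengths_all.min(), 1), lengths_all.max() + 1
        edges = (np.geomspace(lo, hi, bins + 1) if log_scale
                 else np.linspace(lo, hi, bins + 1))
    else:
        edges = np.asarray(bins)
    for sid, sub in tracts.tracts.groupby("id", sort=False):
        counts, _ = np.histogram(sub["bp"], bins=edges)
        for i, c in enumerate(counts):
            rows.append((sid, edges[i], edges[i + 1], int(c)))
    return pd.DataFrame(rows, columns=["id", "bp_low", "bp_high", "count"])
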