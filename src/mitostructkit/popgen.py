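"""Windowed diversity, differentiation and selective-sweep calling.

Operates on haploid variant matrices (organelle genomes are effectively
haploid). Nucleotide diversity pi is the per-base average pairwise
difference among haplotypes; differentiation uses the Weir-Cockerham
variance-components estimator specialized to haploid calls, weighted over
the sites of each window (the convention of the windowed F_ST most variant
toolkits report). Sweep windows combine elevated F_ST with a reduced
cultivated-to-wild diversity ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "VariantMatrix",
    "filter_variants",
    "site_pi",
    "windowed_pi",
    "site_fst_components",
    "windowed_fst",
    "window_table",
    "call_sweeps",
    "write_vcf",
    "read_vcf",
]


@dataclass
class VariantMatrix:
    """Haploid variant calls for a set of samples on a circular reference.

    ``genotypes`` is (n_sites, n_samples) int8: 0 = ref, 1.. = alt alleles,
    -1 = missing. ``positions`` are 1-based and strictly increasing.
    """

    samples: List[str]
    populations: Dict[str, str]
    positions: np.ndarray
    genotypes: np.ndarray
    reference_length: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.genotypes.shape != (len(self.positions), len(self.samples)):
            raise ValueError("genotypes shape must be (n_sites, n_samples)")

    def pop_columns(self, pop: str) -> np.ndarray:
        cols = [i for i, s in enumerate(self.samples) if self.populations.get(s) == pop]
        if not cols:
            raise ValueError(f"no samples in population {pop!r}")
        return np.asarray(cols)

    @property
    def n_sites(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_variants(
    vm: VariantMatrix, maf_min: float = 0.01, max_missing: float = 0.1
) -> VariantMatrix:
    """Drop sites with MAF <= maf_min or missing fraction >= max_missing.

    MAF is computed over non-missing haploid calls; a site whose minor
    allele frequency exceeds ``maf_min`` and whose missing fraction stays
    below ``max_missing`` is kept. Site order is preserved.
    """
    gt = vm.genotypes
    n_samples = gt.shape[1]
    keep = np.ones(vm.n_sites, dtype=bool)
    for i in range(vm.n_sites):
        row = gt[i]
        called = row[row >= 0]
        miss_frac = 1.0 - len(called) / n_samples
        if miss_frac >= max_missing or len(called) == 0:
            keep[i] = False
            continue
        counts = np.bincount(called)
        freqs = counts / counts.sum()
        maf = 1.0 - freqs.max() if len(freqs) > 1 else 0.0
        # minor allele frequency = total frequency of non-major alleles
        if maf <= maf_min:
            keep[i] = False
    return VariantMatrix(
        samples=vm.samples,
        populations=vm.populations,
        positions=vm.positions[keep],
        genotypes=gt[keep],
        reference_length=vm.reference_length,
    )


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def site_pi(calls: np.ndarray) -> float:
    """Per-site pi among haploid calls: (n/(n-1)) * (1 - sum p_a^2)."""
    called = calls[calls >= 0]
    n = len(called)
    if n < 2:
        return 0.0
    counts = np.bincount(called)
    p = counts / n
    return n / (n - 1) * (1.0 - float(np.sum(p**2)))


def _window_starts(L: int, window: int, step: int) -> np.ndarray:
    return np.arange(0, L, step, dtype=np.int64)


def _sites_in_window(positions: np.ndarray, L: int, start: int, window: int) -> np.ndarray:
    idx0 = (positions - 1 - start) % L  # 0-based offset into the window
    return np.nonzero(idx0 < window)[0]


def windowed_pi(
    vm: VariantMatrix, pop: str, window: int = 1000, step: int = 500
) -> pd.DataFrame:
    """Sliding-window pi per bp for one population; windows wrap the circle."""
    cols = vm.pop_columns(pop)
    pis = np.array([site_pi(vm.genotypes[i, cols]) for i in range(vm.n_sites)])
    rows = []
    for s in _window_starts(vm.reference_length, window, step):
        idx = _sites_in_window(vm.positions, vm.reference_length, int(s), window)
        rows.append({"start": int(s), "end": int(s) + window, "pi": pis[idx].sum() / window})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# F_ST (Weir & Cockerham, haploid specialization)
# ---------------------------------------------------------------------------

def site_fst_components(callsA: np.ndarray, callsB: np.ndarray) -> Tuple[float, float]:
    """Per-site W&C variance components (numerator, denominator), haploid.

    For each allele: MSP = sum_i n_i (p_i - pbar)^2 / (r-1) between
    populations, MSG = sum_i n_i p_i (1-p_i) / sum_i (n_i - 1) within,
    n_c = (N - sum n_i^2 / N) / (r-1). The site's contribution to the
    weighted estimator is sum_a (MSP_a - MSG_a) over sum_a
    (MSP_a + (n_c - 1) MSG_a); windows sum components before dividing.
    """
    a = callsA[callsA >= 0]
    b = callsB[callsB >= 0]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        return 0.0, 0.0
    N = n1 + n2
    r = 2
    nc = (N - (n1 * n1 + n2 * n2) / N) / (r - 1)
    n_alleles = int(max(a.max(initial=0), b.max(initial=0))) + 1
    num = den = 0.0
    for al in range(n_alleles):
        p1 = np.mean(a == al)
        p2 = np.mean(b == al)
        pbar = (n1 * p1 + n2 * p2) / N
        if pbar in (0.0, 1.0):
            continue
        msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 - 1 + n2 - 1)
        num += msp - msg
        den += msp + (nc - 1) * msg
    return num, den


def windowed_fst(
    vm: VariantMatrix, popA: str, popB: str, window: int = 1000, step: int = 500
) -> pd.DataFrame:
    """Sliding-window weighted W&C F_ST between two populations.

    Negative estimates are reported as computed, not truncated to zero.
    """
    colsA = vm.pop_columns(popA)
    colsB = vm.pop_columns(popB)
    comps = np.array(
        [site_fst_components(vm.genotypes[i, colsA], vm.genotypes[i, colsB]) for i in range(vm.n_sites)]
    ).reshape(-1, 2)
    rows = []
    for s in _window_starts(vm.reference_length, window, step):
        idx = _sites_in_window(vm.positions, vm.reference_length, int(s), window)
        num = comps[idx, 0].sum() if len(idx) else 0.0
        den = comps[idx, 1].sum() if len(idx) else 0.0
        fst = num / den if den != 0 else float("nan")
        rows.append({"start": int(s), "end": int(s) + window, "fst": fst})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sweep calling
# ---------------------------------------------------------------------------

def window_table(
    vm: VariantMatrix,
    wild: str = "wild",
    cultivated: str = "cultivated",
    window: int = 1000,
    step: int = 500,
) -> pd.DataFrame:
    """Per-window pi_wild, pi_cul, fst and the pi_wild/pi_cul ratio."""
    pw = windowed_pi(vm, wild, window, step).rename(columns={"pi": "pi_wild"})
    pc = windowed_pi(vm, cultivated, window, step)["pi"].rename("pi_cul")
    fs = windowed_fst(vm, wild, cultivated, window, step)["fst"]
    out = pd.concat([pw, pc, fs], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio"] = np.where(out["pi_cul"] > 0, out["pi_wild"] / out["pi_cul"], np.nan)
    return out


def call_sweeps(
    windows: pd.DataFrame,
    fst_min: float = 0.1,
    ratio_min: float = 2.0,
    reference_length: Optional[int] = None,
    allow_infinite_ratio: bool = False,
) -> Tuple[pd.DataFrame, List[Tuple[int, int]]]:
    """Flag sweep windows (fst > fst_min AND ratio > ratio_min); merge regions.

    A window with pi_cul = 0 has an undefined ratio and is not flagged
    unless ``allow_infinite_ratio`` is set and pi_wild > 0. Overlapping or
    adjacent flagged windows merge into regions; if the reference length is
    given, regions wrapping the origin are joined.
    """
    w = windows.copy()
    ratio_ok = w["ratio"] > ratio_min
    if allow_infinite_ratio:
        ratio_ok |= w["ratio"].isna() & (w["pi_wild"] > 0) & (w["pi_cul"] == 0)
    w["sweep"] = (w["fst"] > fst_min) & ratio_ok
    flagged = w.loc[w["sweep"], ["start", "end"]].sort_values("start")
    regions: List[Tuple[int, int]] = []
    for s, e in flagged.itertuples(index=False):
        if regions and s <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], e))
        else:
            regions.append((int(s), int(e)))
    if reference_length and len(regions) > 1:
        first_s, first_e = regions[0]
        last_s, last_e = regions[-1]
        if last_e >= reference_length and (last_e % reference_length) >= first_s:
            regions[0] = (last_s, first_e + reference_length)
            regions.pop()
    return w, regions


# ---------------------------------------------------------------------------
# minimal haploid GT-only VCF I/O
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=mitostructkit
##contig=<ID={contig},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">
"""


def write_vcf(vm: VariantMatrix, path: str | Path, contig: str = "mito") -> None:
    """Write a minimal haploid GT-only VCF (uncompressed text)."""
    lines = [_VCF_HEADER.format(contig=contig, length=vm.reference_length)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(vm.samples) + "\n")
    # allele letters are placeholders: the matrix carries indices only
    alleles = ["A", "C", "G", "T"]
    for i, pos in enumerate(vm.positions):
        row = vm.genotypes[i]
        n_alt = max(1, int(row.max(initial=1)))
        alt = ",".join(alleles[1 : n_alt + 1])
        gts = "\t".join("." if g < 0 else str(int(g)) for g in row)
        lines.append(f"{contig}\t{pos}\t.\tA\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
    Path(path).write_text("".join(lines))


def read_vcf(path: str | Path, populations: Dict[str, str], reference_length: int) -> VariantMatrix:
    """Read a haploid GT-only VCF through pysam."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    positions: List[int] = []
    rows: List[List[int]] = []
    for rec in vf:
        positions.append(rec.pos)
        row = []
        for s in samples:
            gt = rec.samples[s]["GT"]
            allele = gt[0] if gt else None
            row.append(-1 if allele is None else int(allele))
        rows.append(row)
    vf.close()
    return VariantMatrix(
        samples=samples,
        populations=populations,
        positions=np.asarray(positions, dtype=np.int64),
        genotypes=np.asarray(rows, dtype=np.int8),
        reference_length=reference_length,
    )
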