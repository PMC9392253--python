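"""Repeat census of a circular mitogenome.

Detects repeat pairs by comparing the genome against itself (both strands),
classifies them into the four length classes used throughout the package
(<100, 100-500, 501-1000, >1000 bp), identifies plastid-derived segments by
cross-comparison against the plastid genome, and relates repeat content to
genome size across species with phylogenetic generalized least squares
(PGLS) under a Brownian-motion covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._align import LocalHit, local_hits
from .sequences import CircularSequence, revcomp

__all__ = [
    "RepeatPair",
    "RepeatSummary",
    "PGLSFit",
    "LENGTH_CLASSES",
    "find_repeats",
    "classify_repeats",
    "length_class",
    "identify_plastid_derived",
    "merge_intervals",
    "pgls_fit",
    "genome_stats",
    "repeat_summary",
    "repeats_to_frame",
]

LENGTH_CLASSES = ("<100", "100–500", "501–1000", ">1000")


@dataclass(frozen=True)
class RepeatPair:
    """Two loci of a repeated sequence within one circular genome.

    Loci are 0-based half-open on the forward strand; an end may exceed the
    genome length, meaning the locus wraps across the origin. ``orientation``
    is "direct" when both copies lie on the same strand and "inverted"
    otherwise.
    """

    locusA: Tuple[int, int]
    locusB: Tuple[int, int]
    length: int
    identity: float
    orientation: str  # "direct" | "inverted"

    def __post_init__(self) -> None:
        if self.locusA == self.locusB:
            raise ValueError("repeat loci must differ")
        if self.orientation not in ("direct", "inverted"):
            raise ValueError("orientation must be 'direct' or 'inverted'")
        if not (0 <= self.identity <= 100):
            raise ValueError("identity must be in [0, 100]")

    @property
    def length_class(self) -> str:
        return length_class(self.length)


def length_class(length: int) -> str:
    """Length class with closed integer bins: <100; [100,500]; [501,1000]; >1000."""
    if length < 100:
        return LENGTH_CLASSES[0]
    if length <= 500:
        return LENGTH_CLASSES[1]
    if length <= 1000:
        return LENGTH_CLASSES[2]
    return LENGTH_CLASSES[3]


def classify_repeats(pairs: Sequence[RepeatPair]) -> Dict[str, List[RepeatPair]]:
    """Partition repeat pairs into the four length classes."""
    out: Dict[str, List[RepeatPair]] = {c: [] for c in LENGTH_CLASSES}
    for p in pairs:
        out[p.length_class].append(p)
    return out


# ---------------------------------------------------------------------------
# repeat detection
# ---------------------------------------------------------------------------

def _hit_to_pair(h: LocalHit, L: int, inverted: bool) -> Optional[RepeatPair]:
    """Normalize a self-comparison hit to a canonical RepeatPair, or None."""
    qs, qe = h.qstart, h.qend
    if inverted:
        # subject was the reverse complement; map back to forward coordinates
        ss = L - h.send
        se = L - h.sstart
    else:
        ss, se = h.sstart, h.send
    a, b = (qs, qe), (ss, se)
    if a == b:
        return None
    if a[0] > b[0]:
        a, b = b, a
    return RepeatPair(
        locusA=a,
        locusB=b,
        length=h.length,
        identity=round(h.identity, 2),
        orientation="inverted" if inverted else "direct",
    )


def _norm_key(p: RepeatPair, L: int) -> Tuple:
    a = (p.locusA[0] % L, (p.locusA[0] % L) + p.length)
    b = (p.locusB[0] % L, (p.locusB[0] % L) + p.length)
    if a > b:
        a, b = b, a
    return (a, b, p.orientation)


def find_repeats(
    genome: CircularSequence | str,
    min_word: int = 7,
    evalue_max: float = 1e-6,
    max_ambiguous_frac: float = 0.05,
) -> List[RepeatPair]:
    """Detect repeat pairs within one circular genome.

    Self seed-and-extend comparison on both strands with Karlin-Altschul
    e-values against the genome as both query and subject; hits crossing the
    circular origin are recovered by rescanning a half-length rotation and
    normalizing coordinates. Output is sorted by (locusA.start, locusB.start).
    """
    seq = genome.seq if isinstance(genome, CircularSequence) else genome
    seq = seq.upper()
    L = len(seq)
    if L < 2 * min_word:
        raise ValueError("genome shorter than two seed words")
    n_bad = sum(1 for c in seq if c not in "ACGT")
    if n_bad > max_ambiguous_frac * L:
        raise ValueError(
            f"{n_bad}/{L} non-ACGT characters exceed the allowed fraction {max_ambiguous_frac}"
        )

    found: Dict[Tuple, RepeatPair] = {}
    offset = L // 2
    for rot in (0, offset):
        s = seq[rot:] + seq[:rot]
        for inverted in (False, True):
            subject = revcomp(s) if inverted else s
            hits = local_hits(
                s, subject, word=min_word, evalue_max=evalue_max, self_mode=not inverted
            )
            for h in hits:
                p = _hit_to_pair(h, L, inverted)
                if p is None:
                    continue
                if rot:
                    p = RepeatPair(
                        locusA=((p.locusA[0] + rot) % L, (p.locusA[0] + rot) % L + p.length),
                        locusB=((p.locusB[0] + rot) % L, (p.locusB[0] + rot) % L + p.length),
                        length=p.length,
                        identity=p.identity,
                        orientation=p.orientation,
                    )
                key = _norm_key(p, L)
                if key not in found:
                    a, b = key[0], key[1]
                    found[key] = RepeatPair(a, b, p.length, p.identity, p.orientation)
    pairs = _drop_inverted_self_overlaps(list(found.values()))
    pairs = _drop_contained(pairs, L)
    pairs.sort(key=lambda p: (p.locusA[0], p.locusB[0]))
    return pairs


def _circ_contains(outer: Tuple[int, int], inner: Tuple[int, int], L: int) -> bool:
    off = (inner[0] - outer[0]) % L
    return off + (inner[1] - inner[0]) <= outer[1] - outer[0]


def _drop_contained(pairs: List[RepeatPair], L: int) -> List[RepeatPair]:
    """Drop hits contained in a larger hit of the same pair.

    The half-rotation rescan can split a hit crossing the rotation cut into
    fragments; a fragment is recognized by both its loci lying (circularly)
    within the corresponding loci of a longer same-orientation hit.
    """
    keep = []
    for p in pairs:
        redundant = False
        for q in pairs:
            if q is p or q.length <= p.length or q.orientation != p.orientation:
                continue
            if (_circ_contains(q.locusA, p.locusA, L) and _circ_contains(q.locusB, p.locusB, L)) or (
                _circ_contains(q.locusA, p.locusB, L) and _circ_contains(q.locusB, p.locusA, L)
            ):
                redundant = True
                break
        if not redundant:
            keep.append(p)
    return keep


def _drop_inverted_self_overlaps(pairs: List[RepeatPair]) -> List[RepeatPair]:
    """Drop inverted hits whose two loci are the same palindromic interval."""
    out = []
    for p in pairs:
        if p.orientation == "inverted" and p.locusA == p.locusB:
            continue
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# plastid-derived sequence
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of 0-based half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def identify_plastid_derived(
    mito: CircularSequence | str,
    plastid: CircularSequence | str,
    evalue_max: float = 1e-6,
    word: int = 7,
) -> Tuple[List[Tuple[int, int]], int, float]:
    """Plastid-derived intervals on the mitogenome.

    Cross-comparison of the mitogenome against the plastid genome on both
    strands; overlapping hit intervals on the mitogenome are merged. Returns
    (merged intervals, total bp, percent of mitogenome to 2 decimals).
    """
    mseq = (mito.seq if isinstance(mito, CircularSequence) else mito).upper()
    pseq = (plastid.seq if isinstance(plastid, CircularSequence) else plastid).upper()
    if not mseq or not pseq:
        raise ValueError("both sequences must be non-empty")
    ivs: List[Tuple[int, int]] = []
    for subject in (pseq, revcomp(pseq)):
        for h in local_hits(mseq, subject, word=word, evalue_max=evalue_max, self_mode=False):
            ivs.append((h.qstart, h.qend))
    merged = merge_intervals(ivs)
    total = sum(e - s for s, e in merged)
    percent = round(100.0 * total / len(mseq), 2)
    return merged, total, percent


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatSummary:
    per_class_counts: Dict[str, int]
    total_count: int
    total_length: int  # each pair counted once
    genome_size: int
    gc_content: float


def genome_stats(genome: CircularSequence | str) -> Tuple[int, float]:
    """(size bp, GC percent to 2 decimals); ambiguous bases excluded from the denominator."""
    seq = (genome.seq if isinstance(genome, CircularSequence) else genome).upper()
    counts = {c: seq.count(c) for c in "ACGT"}
    denom = sum(counts.values())
    gc = 100.0 * (counts["G"] + counts["C"]) / denom if denom else float("nan")
    return len(seq), round(gc, 2)


def repeat_summary(
    genome: CircularSequence | str, pairs: Sequence[RepeatPair], per_copy: bool = False
) -> RepeatSummary:
    """Per-class counts and total repeat length (per pair by default)."""
    classes = classify_repeats(pairs)
    counts = {c: len(v) for c, v in classes.items()}
    mult = 2 if per_copy else 1
    size, gc = genome_stats(genome)
    return RepeatSummary(
        per_class_counts=counts,
        total_count=sum(counts.values()),
        total_length=mult * sum(p.length for p in pairs),
        genome_size=size,
        gc_content=gc,
    )


def repeats_to_frame(pairs: Sequence[RepeatPair]) -> pd.DataFrame:
    rows = [
        {
            "startA": p.locusA[0],
            "endA": p.locusA[1],
            "strandA": "+",
            "startB": p.locusB[0],
            "endB": p.locusB[1],
            "strandB": "+" if p.orientation == "direct" else "-",
            "length": p.length,
            "identity": p.identity,
            "class": p.length_class,
            "orientation": p.orientation,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "startA",
            "endA",
            "strandA",
            "startB",
            "endB",
            "strandB",
            "length",
            "identity",
            "class",
            "orientation",
        ],
    )


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PGLSFit:
    """Generalized least squares fit under Brownian-motion trait covariance."""

    slope: float
    intercept: float
    r2_adj: float
    p_value: float
    tree_id: str
    model: str = "BM-correlation"


def _bm_covariance(tree, labels: List[str]) -> np.ndarray:
    """V_ij = shared root-to-tip path length, from a dendropy tree."""
    depths = {}
    for leaf in tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.distance_from_root()
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                V[i, j] = depths[a]
            else:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                V[i, j] = 0.5 * (depths[a] + depths[b] - d)
    return V


def pgls_fit(x: pd.Series, y: pd.Series, tree, tree_id: str = "") -> PGLSFit:
    """PGLS regression of y on x with Brownian-motion covariance from ``tree``.

    ``x`` and ``y`` are indexed by species labels matching the tree's tips;
    branch lengths must be positive. Reports the slope, adjusted R**2 and
    the F-test p-value of the regression.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    labels = list(x.index)
    if set(labels) != tips or list(y.index) != labels:
        missing = sorted(tips ^ set(labels)) or sorted(set(y.index) ^ set(labels))
        raise ValueError(f"tip/sample mismatch: {missing}")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and (edge.length is None or edge.length <= 0):
            raise ValueError("all branch lengths must be > 0")
    V = _bm_covariance(tree, labels)
    X = sm.add_constant(np.asarray(x, dtype=float))
    res = sm.GLS(np.asarray(y, dtype=float), X, sigma=V).fit()
    return PGLSFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2_adj=float(res.rsquared_adj),
        p_value=float(res.f_pvalue),
        tree_id=tree_id,
    )
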