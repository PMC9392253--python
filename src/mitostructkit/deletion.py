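"""Depth-ratio genotyping of large mitogenome deletions.

A candidate region's mean read depth (Idep) divided by the sample's
whole-genome mean depth (Wdep) separates carriers from non-carriers: the
empirical ratio bands are low (0.24-0.72) for absence and high
(6.94-142.98) for presence. Carrier frequencies are compared between groups
with Pearson chi-square tests; homologous-sequence totals and ORFs
characterize the deleted region itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .repeats import merge_intervals
from .sequences import revcomp

__all__ = [
    "DepthCall",
    "CarrierTable",
    "DEFAULT_BANDS",
    "depth_ratio",
    "classify_presence",
    "carrier_frequencies",
    "merge_homology_hits",
    "orf_scan",
]

DEFAULT_BANDS = ((0.24, 0.72), (6.94, 142.98))


@dataclass(frozen=True)
class DepthCall:
    sample_id: str
    region: Tuple[int, int]
    idep: float
    wdep: float
    ratio: float  # NaN when wdep == 0
    call: str  # "present" | "absent" | "ambiguous"


def depth_ratio(
    region_depths: Sequence[float], wdep: float, use_median: bool = False
) -> Tuple[float, float]:
    """(Idep, Idep/Wdep) from per-base depths over the region.

    Idep is the mean depth across region bases (median with
    ``use_median``); the ratio is NaN when Wdep is 0.
    """
    d = np.asarray(region_depths, dtype=float)
    if np.any(d < 0) or wdep < 0:
        raise ValueError("depths must be >= 0")
    idep = float(np.median(d)) if use_median else float(np.mean(d))
    ratio = idep / wdep if wdep > 0 else float("nan")
    return idep, ratio


def classify_presence(
    ratio: float,
    threshold: float = 2.0,
    two_band: bool = False,
    bands: Tuple[Tuple[float, float], Tuple[float, float]] = DEFAULT_BANDS,
) -> str:
    """Presence call from a depth ratio.

    Single-threshold mode (default): present iff ratio >= threshold. The
    two-band mode keeps the empirical gap: ratios strictly between the low
    band's upper edge and the high band's lower edge are "ambiguous".
    """
    if math.isnan(ratio):
        return "ambiguous"
    if two_band:
        (_, lo_max), (hi_min, _) = bands
        if ratio <= lo_max:
            return "absent"
        if ratio >= hi_min:
            return "present"
        return "ambiguous"
    return "present" if ratio >= threshold else "absent"


# ---------------------------------------------------------------------------
# carrier frequencies and group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarrierTable:
    """Per-group carrier counts and pairwise Pearson chi-square tests."""

    groups: pd.DataFrame  # group, n_present, n_total, percent
    pairwise: pd.DataFrame  # group_a, group_b, chi2, p_value


def _pearson_chi2(table: np.ndarray, yates: bool = False) -> Tuple[float, float]:
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def carrier_frequencies(
    calls: Sequence[DepthCall] | pd.DataFrame,
    group_map: Dict[str, str],
    yates: bool = False,
) -> CarrierTable:
    """Carrier frequency per group with pairwise chi-square comparisons.

    Ambiguous calls are excluded from the counts. The chi-square statistic
    is Pearson's without continuity correction by default (``yates``
    enables it); p-values come from the chi-square distribution with 1 df.
    """
    if isinstance(calls, pd.DataFrame):
        records = calls.to_dict("records")
        records = [
            DepthCall(r["sample_id"], (0, 0), r.get("Idep", 0), r.get("Wdep", 0), r.get("ratio", float("nan")), r["call"])
            for r in records
        ]
    else:
        records = list(calls)
    per_group: Dict[str, List[str]] = {}
    for c in records:
        g = group_map.get(c.sample_id)
        if g is None:
            raise KeyError(f"sample {c.sample_id!r} missing from group map")
        per_group.setdefault(g, []).append(c.call)
    rows = []
    for g in sorted(per_group):
        calls_g = [c for c in per_group[g] if c != "ambiguous"]
        n_present = sum(1 for c in calls_g if c == "present")
        n_total = len(calls_g)
        rows.append(
            {
                "group": g,
                "n_present": n_present,
                "n_total": n_total,
                "percent": round(100.0 * n_present / n_total, 2) if n_total else float("nan"),
            }
        )
    groups = pd.DataFrame(rows)
    pair_rows = []
    glist = list(groups["group"])
    for i in range(len(glist)):
        for j in range(i + 1, len(glist)):
            a = groups.iloc[i]
            b = groups.iloc[j]
            tab = np.array(
                [
                    [a["n_present"], a["n_total"] - a["n_present"]],
                    [b["n_present"], b["n_total"] - b["n_present"]],
                ],
                dtype=float,
            )
            if tab.sum(axis=1).min() == 0 or tab.sum(axis=0).min() == 0:
                chi2, p = 0.0, 1.0
            else:
                chi2, p = _pearson_chi2(tab, yates=yates)
            pair_rows.append(
                {"group_a": glist[i], "group_b": glist[j], "chi2": chi2, "p_value": p}
            )
    return CarrierTable(groups=groups, pairwise=pd.DataFrame(pair_rows))


# ---------------------------------------------------------------------------
# homology totals and ORFs of the deleted region
# ---------------------------------------------------------------------------

def merge_homology_hits(
    hits: Iterable[Tuple[int, int]], region_length: int, min_hit_len: int = 100
) -> Tuple[int, float]:
    """Total non-overlapping homologous bp on a target region.

    Hits of ``min_hit_len`` bp or shorter are discarded (the filter keeps
    hits strictly longer than 100 bp by default); the rest are unioned.
    Returns (total bp, percent of the region to 2 decimals).
    """
    kept = [(s, e) for s, e in hits if (e - s) > min_hit_len]
    merged = merge_intervals(kept)
    total = sum(e - s for s, e in merged)
    return total, round(100.0 * total / region_length, 2)


_STOPS = {"TAA", "TAG", "TGA"}


def orf_scan(sequence: str, min_len: int = 150) -> List[Tuple[int, int, str]]:
    """ATG-to-stop ORFs of at least ``min_len`` bp (stop included) on both strands.

    Every qualifying ATG..stop pair is reported, including nested starts.
    Coordinates are 0-based half-open on the forward strand; the third
    element is the strand ("+" or "-"). ORFs lacking an in-frame stop are
    not reported.
    """
    seq = sequence.upper()
    L = len(seq)
    out: List[Tuple[int, int, str]] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            # scan codons right-to-left remembering the next in-frame stop
            next_stop = None
            starts: List[Tuple[int, int]] = []  # (start, stop_end)
            for i in reversed(range(frame, L - 2, 3)):
                codon = s[i : i + 3]
                if codon in _STOPS:
                    next_stop = i + 3
                elif codon == "ATG" and next_stop is not None:
                    if next_stop - i >= min_len:
                        starts.append((i, next_stop))
            for i, j in starts:
                if strand == "+":
                    out.append((i, j, "+"))
                else:
                    out.append((L - j, L - i, "-"))
    out.sort()
    return out
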