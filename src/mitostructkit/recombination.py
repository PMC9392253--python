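"""Repeat-mediated homologous recombination frequency from long reads.

For a repeat pair with copies b and e, each copy plus 200 bp of upstream and
downstream context defines a reference form (a-b-c and d-e-f). Recombinant
forms swap the flanks across the copies: all of {a,d} x {b,e} x {c,f} minus
the two references (six forms), collapsing to the two forms a-b-f and d-b-c
when the copies are exactly identical. Long reads are assigned to the single
form they match near-perfectly across both flanks; the recombination
frequency of the pair is the fraction of informative reads supporting a
recombinant form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from ._align import evalue as _ka_evalue
from .repeats import RepeatPair, LENGTH_CLASSES, length_class
from .sequences import CircularSequence, revcomp

__all__ = [
    "RecombAssay",
    "ActivitySummary",
    "build_mito_read_set",
    "build_recombinant_references",
    "assign_reads",
    "recombination_frequency",
    "activity_summary",
    "activity_percent",
]


@dataclass
class RecombAssay:
    """One repeat pair's reference/recombinant forms and read-support counts."""

    pair: RepeatPair
    flank: int
    reference_forms: Dict[str, str]
    recombinant_forms: Dict[str, str]
    n_ref: int = 0
    n_recomb: int = 0
    n_uninformative: int = 0

    @property
    def frequency(self) -> float:
        """Recombination frequency in percent; NaN when no informative reads."""
        return recombination_frequency(self)


def recombination_frequency(assay: "RecombAssay") -> float:
    """100 * n_recomb / (n_ref + n_recomb); NaN when the denominator is 0."""
    denom = assay.n_ref + assay.n_recomb
    if denom == 0:
        return float("nan")
    return 100.0 * assay.n_recomb / denom


# ---------------------------------------------------------------------------
# form construction
# ---------------------------------------------------------------------------

def build_recombinant_references(
    genome: CircularSequence, pair: RepeatPair, flank: int = 200
) -> RecombAssay:
    """Reference and recombinant junction forms for one repeat pair.

    Copy b's context is read on the forward strand; copy e's context is read
    on the strand that aligns with b (reverse complement for inverted
    pairs), so every form is written in b's orientation. Reads are compared
    on both strands downstream, so this convention is free of loss.
    """
    L = len(genome)
    (s1, e1), (s2, e2) = pair.locusA, pair.locusB
    # flank must not run into the other copy
    gap_ab = (s2 - e1) % L
    gap_ba = (s1 - e2) % L
    if gap_ab < flank or gap_ba < flank:
        raise ValueError(
            "flank overlaps the other repeat copy: copies too close for the assay"
        )
    a = genome.fetch(s1 - flank, s1)
    b = genome.fetch(s1, e1)
    c = genome.fetch(e1, e1 + flank)
    if pair.orientation == "direct":
        d = genome.fetch(s2 - flank, s2)
        e = genome.fetch(s2, e2)
        f = genome.fetch(e2, e2 + flank)
    else:
        # aligned strand of copy e is the reverse complement
        d = revcomp(genome.fetch(e2, e2 + flank))
        e = revcomp(genome.fetch(s2, e2))
        f = revcomp(genome.fetch(s2 - flank, s2))

    refs = {"ref_abc": a + b + c, "ref_def": d + e + f}
    if b == e:
        recombs = {"rec_abf": a + b + f, "rec_dbc": d + b + c}
    else:
        recombs = {
            "rec_abf": a + b + f,
            "rec_aec": a + e + c,
            "rec_aef": a + e + f,
            "rec_dbc": d + b + c,
            "rec_dbf": d + b + f,
            "rec_dec": d + e + c,
        }
    return RecombAssay(pair=pair, flank=flank, reference_forms=refs, recombinant_forms=recombs)


# ---------------------------------------------------------------------------
# read filtering and assignment
# ---------------------------------------------------------------------------

def _chunk_coverage(read: str, reference: str, chunk: int = 100, min_ident: float = 80.0) -> float:
    """Fraction of non-overlapping read chunks matching the circular reference."""
    ref2 = reference + reference[: min(len(reference), 4 * chunk)]
    n = max(1, len(read) // chunk)
    hits = 0
    for i in range(n):
        piece = read[i * chunk : (i + 1) * chunk]
        if len(piece) < chunk // 2:
            continue
        best = math.inf
        for q in (piece, revcomp(piece)):
            r = edlib.align(q, ref2, mode="HW", task="distance")
            best = min(best, r["editDistance"])
        if 100.0 * (1 - best / len(piece)) >= min_ident:
            hits += 1
    return hits / n


def build_mito_read_set(
    reads: Sequence,
    mito_ref: CircularSequence | str,
    plastid_ref: CircularSequence | str,
    evalue_max: float = 1e-100,
    max_plastid_cov: float = 0.85,
) -> List:
    """Keep reads anchored in the mitogenome, dropping putative plastid reads.

    A read is mitochondrial if it carries a near-exact anchor long enough
    that its Karlin-Altschul e-value against the mitogenome is at or below
    ``evalue_max`` (a ~200-bp near-exact match is orders of magnitude below
    1e-100); it is discarded as plastid if chunks covering more than
    ``max_plastid_cov`` of its length match the plastid genome.
    """
    mseq = mito_ref.seq if isinstance(mito_ref, CircularSequence) else mito_ref
    pseq = plastid_ref.seq if isinstance(plastid_ref, CircularSequence) else plastid_ref
    if not mseq or not pseq:
        raise ValueError("references must be non-empty")
    if len(reads) == 0:
        warnings.warn("empty read set", stacklevel=2)
        return []
    # anchor bp needed: smallest exact run whose e-value clears the cutoff
    anchor_bp = 200
    while _ka_evalue(anchor_bp, len(mseq), 50_000) > evalue_max and anchor_bp < 1000:
        anchor_bp += 50
    kept = []
    for read in reads:
        seq = read.seq if hasattr(read, "seq") else str(read)
        mito_cov = _chunk_coverage(seq, mseq, chunk=anchor_bp, min_ident=95.0)
        if mito_cov == 0.0:
            continue
        plastid_cov = _chunk_coverage(seq, pseq)
        if plastid_cov > max_plastid_cov:
            continue
        kept.append(read)
    return kept


def assign_reads(
    reads: Sequence,
    assay: RecombAssay,
    min_identity: float = 99.0,
    flank_required: int = 200,
) -> RecombAssay:
    """Count read support for reference vs recombinant forms.

    A read supports a form when the form's best (edit-distance) alignment
    into the read has identity above ``min_identity`` over the full form --
    which forces coverage of both ``flank_required``-bp flanks, since a
    missing flank alone costs far more than the identity budget. Reads
    supporting no form, or tied between several best forms, are
    uninformative. Counts accumulate on a copy of ``assay``.
    """
    if flank_required > assay.flank:
        raise ValueError("flank_required cannot exceed the constructed flank")
    forms = {**assay.reference_forms, **assay.recombinant_forms}
    n_ref = n_recomb = n_unin = 0
    for read in reads:
        seq = read.seq if hasattr(read, "seq") else str(read)
        rc = revcomp(seq)
        best_forms: List[str] = []
        best_dist = None
        for name, form in forms.items():
            # identity over the form; unaligned flank bp count as edits.
            # forms beyond the identity budget cannot be supporting, so the
            # edit-distance search is capped there (exact, and much faster)
            budget = int(len(form) * (1.0 - min_identity / 100.0))
            if len(seq) < len(form) - budget:
                continue
            d = -1
            for target in (seq, rc):
                r = edlib.align(form, target, mode="HW", task="distance", k=budget)
                if r["editDistance"] >= 0 and (d < 0 or r["editDistance"] < d):
                    d = r["editDistance"]
            if d < 0:
                continue
            ident = 100.0 * (1.0 - d / len(form))
            if ident <= min_identity:
                continue
            if best_dist is None or d < best_dist:
                best_dist = d
                best_forms = [name]
            elif d == best_dist:
                best_forms.append(name)
        if best_dist is None or len(best_forms) != 1:
            n_unin += 1
        elif best_forms[0] in assay.reference_forms:
            n_ref += 1
        else:
            n_recomb += 1
    return RecombAssay(
        pair=assay.pair,
        flank=assay.flank,
        reference_forms=assay.reference_forms,
        recombinant_forms=assay.recombinant_forms,
        n_ref=assay.n_ref + n_ref,
        n_recomb=assay.n_recomb + n_recomb,
        n_uninformative=assay.n_uninformative + n_unin,
    )


# ---------------------------------------------------------------------------
# activity summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivitySummary:
    """Per length-class recombination activity and frequency-band counts."""

    per_class: pd.DataFrame  # columns: class, n_active, n_total, percent_active
    n_freq_lt1: int
    n_freq_gt20: int
    n_freq_gt50: int


def activity_percent(n_active: int, n_total: int) -> float:
    """Active-pair percentage to 2 decimals; NaN when the class is empty."""
    if n_total == 0:
        return float("nan")
    if n_active > n_total:
        raise ValueError("n_active cannot exceed n_total")
    return round(100.0 * n_active / n_total, 2)


def activity_summary(assays: Sequence[RecombAssay], min_support: int = 1) -> ActivitySummary:
    """Summarize which repeat pairs show recombination activity.

    A pair is active when at least ``min_support`` reads support a
    recombinant form. Frequency bands count active pairs with frequency
    below 1% and above 20% / 50%.
    """
    rows = []
    lt1 = gt20 = gt50 = 0
    by_class: Dict[str, List[RecombAssay]] = {c: [] for c in LENGTH_CLASSES}
    for a in assays:
        by_class[a.pair.length_class].append(a)
    for cls in LENGTH_CLASSES:
        group = by_class[cls]
        n_active = sum(1 for a in group if a.n_recomb >= min_support)
        rows.append(
            {
                "class": cls,
                "n_active": n_active,
                "n_total": len(group),
                "percent_active": activity_percent(n_active, len(group)),
            }
        )
    for a in assays:
        if a.n_recomb >= min_support:
            f = recombination_frequency(a)
            if math.isnan(f):
                continue
            if f < 1.0:
                lt1 += 1
            if f > 20.0:
                gt20 += 1
            if f > 50.0:
                gt50 += 1
    return ActivitySummary(
        per_class=pd.DataFrame(rows), n_freq_lt1=lt1, n_freq_gt20=gt20, n_freq_gt50=gt50
    )
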