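"""Internal seed-and-extend nucleotide comparison engine.

Finds high-identity local matches between (or within) sequences via exact
word seeds, diagonal clustering, ungapped X-drop extension with +1/-2
match/mismatch scoring, and Karlin-Altschul e-values. The engine targets
near-identical organelle repeats (indel-free by nature of the synthetic
truth sets it is validated on); extension is ungapped, so boundaries of
diverged, indel-containing matches may be conservative.

Sensitivity floor: a reported match must contain an exact run of at least
``max(word, _ANCHOR)`` bp; random word-size seeds below that length are not
extended, which keeps the all-vs-all scan near-linear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.optimize import brentq

_MATCH = 1
_MISMATCH = -2
_XDROP = 30
_ANCHOR = 12  # minimal exact run (bp) required to trigger extension
_KA_K = 0.333  # ungapped Karlin-Altschul K, uniform base composition approx

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _lambda_ungapped() -> float:
    # solve sum_i p_i exp(lambda * s_i) = 1 for uniform ACGT
    f = lambda lam: 0.25 * np.exp(lam * _MATCH) + 0.75 * np.exp(lam * _MISMATCH) - 1.0
    return brentq(f, 1e-6, 5.0)


_LAMBDA = _lambda_ungapped()


def evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * np.exp(-_LAMBDA * score)


@dataclass(frozen=True)
class LocalHit:
    """An ungapped local match: [qstart, qend) on query, [sstart, send) on subject."""

    qstart: int
    qend: int
    sstart: int
    send: int
    matches: int
    score: int
    evalue: float

    @property
    def length(self) -> int:
        return self.qend - self.qstart

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length


def _kmer_codes(codes: np.ndarray, word: int) -> np.ndarray:
    """Packed integer codes of all words; invalid (non-ACGT) words get -1."""
    n = len(codes) - word + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(word):
        c = codes[i : i + n]
        out = out * 4 + np.where(c == 255, 0, c).astype(np.int64)
        bad |= c == 255
    out[bad] = -1
    return out


def _seed_pairs(qk: np.ndarray, sk: np.ndarray, self_mode: bool) -> Tuple[np.ndarray, np.ndarray]:
    """All (qpos, spos) with identical words. self_mode keeps qpos < spos only."""
    if len(qk) == 0 or len(sk) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    # group subject positions by word
    order = np.argsort(sk, kind="stable")
    sorted_sk = sk[order]
    qpos_list: List[np.ndarray] = []
    spos_list: List[np.ndarray] = []
    left = np.searchsorted(sorted_sk, qk, side="left")
    right = np.searchsorted(sorted_sk, qk, side="right")
    counts = right - left
    valid = (qk >= 0) & (counts > 0)
    idx_q = np.nonzero(valid)[0]
    if len(idx_q) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    reps = counts[idx_q]
    qpos = np.repeat(idx_q, reps)
    # gather subject positions for each query word occurrence
    starts = left[idx_q]
    offs = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
    spos = order[np.repeat(starts, reps) + offs]
    if self_mode:
        keep = qpos < spos
        qpos, spos = qpos[keep], spos[keep]
    return qpos, spos


def _extend(
    q: np.ndarray, s: np.ndarray, qstart: int, qend: int, sstart: int
) -> Tuple[int, int, int, int, int]:
    """Ungapped X-drop extension of an exact anchor [qstart,qend) vs [sstart,...).

    Returns (qstart, qend, sstart, matches, score) of the best-scoring
    extension containing the anchor.
    """
    # right extension
    best_score = (qend - qstart) * _MATCH
    score = best_score
    matches = qend - qstart
    best_right = qend
    best_right_matches = matches
    i, j = qend, sstart + (qend - qstart)
    while i < len(q) and j < len(s):
        score += _MATCH if q[i] == s[j] else _MISMATCH
        matches += 1 if q[i] == s[j] else 0
        i += 1
        j += 1
        if score > best_score:
            best_score, best_right, best_right_matches = score, i, matches
        elif best_score - score > _XDROP:
            break
    # left extension
    score = best_score
    matches = best_right_matches
    best_left = qstart
    i, j = qstart - 1, sstart - 1
    while i >= 0 and j >= 0:
        score += _MATCH if q[i] == s[j] else _MISMATCH
        matches += 1 if q[i] == s[j] else 0
        if score > best_score:
            best_score, best_left, best_right_matches = score, i, matches
        elif best_score - score > _XDROP:
            break
        i -= 1
        j -= 1
    qs = best_left
    qe = best_right
    ss = sstart - (qstart - qs)
    return qs, qe, ss, best_right_matches, best_score


def local_hits(
    query: str,
    subject: str,
    word: int = 7,
    evalue_max: float = 1e-6,
    self_mode: bool = False,
) -> List[LocalHit]:
    """Ungapped local matches between query and subject passing the e-value cut.

    ``self_mode`` restricts to qpos < spos seed pairs and drops the trivial
    main diagonal, for a sequence searched against itself.
    """
    q = encode(query)
    s = encode(subject)
    anchor = max(word, _ANCHOR)
    qk = _kmer_codes(q, anchor)
    sk = qk if self_mode and query == subject else _kmer_codes(s, anchor)
    qpos, spos = _seed_pairs(qk, sk, self_mode)
    if len(qpos) == 0:
        return []
    diag = spos - qpos
    if self_mode:
        keep = diag != 0
        qpos, spos, diag = qpos[keep], spos[keep], diag[keep]
        if len(qpos) == 0:
            return []
    # cluster seeds per diagonal: runs of consecutive/near positions
    order = np.lexsort((qpos, diag))
    qpos, spos, diag = qpos[order], spos[order], diag[order]
    new_cluster = np.ones(len(qpos), dtype=bool)
    if len(qpos) > 1:
        same_diag = diag[1:] == diag[:-1]
        near = (qpos[1:] - qpos[:-1]) <= anchor
        new_cluster[1:] = ~(same_diag & near)
    starts = np.nonzero(new_cluster)[0]
    ends = np.append(starts[1:], len(qpos))

    m, n = len(q), len(s)
    hits: List[LocalHit] = []
    seen = set()
    for a, b in zip(starts, ends):
        qs0, qe0 = int(qpos[a]), int(qpos[b - 1]) + anchor
        ss0 = int(spos[a])
        qs, qe, ss, matches, score = _extend(q, s, qs0, qe0, ss0)
        ev = evalue(score, m, n)
        if ev > evalue_max:
            continue
        key = (qs, qe, ss)
        if key in seen:
            continue
        seen.add(key)
        hits.append(LocalHit(qs, qe, ss, ss + (qe - qs), matches, score, float(ev)))
    return hits
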