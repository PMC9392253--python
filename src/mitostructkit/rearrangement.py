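"""Genome rearrangement: signed inversion distance and rearrangement rates.

Circular plant mitogenomes are compared as signed orders of collinear
blocks. The minimum number of inversions separating two such orders is
computed exactly with Hannenhalli–Pevzner theory (breakpoint-graph cycles,
hurdles and the fortress correction) after reducing the circular problem to
a linear one. Event counts are converted to rearrangement rates in events
per million years, either per branch of a dated tree or as pairwise rates
using twice the divergence time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "SignedPermutation",
    "RateEstimate",
    "SharedFraction",
    "canonicalize_circular",
    "inversion_distance",
    "linear_inversion_distance",
    "blocks_from_anchors",
    "pairwise_rate",
    "branch_rate",
    "tree_rates",
]


@dataclass(frozen=True)
class SignedPermutation:
    """A circular signed block order for one genome.

    ``blocks`` holds signed integers whose absolute values are a permutation
    of 1..n; the order is read around the circle, so any rotation (and the
    reflection with all signs flipped) denotes the same molecule.
    """

    blocks: Tuple[int, ...]
    genome_id: str = ""

    def __post_init__(self) -> None:
        vals = sorted(abs(b) for b in self.blocks)
        n = len(self.blocks)
        if n == 0 or vals != list(range(1, n + 1)) or 0 in self.blocks:
            raise ValueError(
                f"blocks must be signed integers with |values| a permutation of 1..n, got {self.blocks}"
            )

    @property
    def n(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class RateEstimate:
    """Rearrangement rate in events per million years (Mya)."""

    events: int
    time_mya: float
    mode: str  # "pairwise" | "branch"
    rate: float


@dataclass(frozen=True)
class SharedFraction:
    shared_bp: int
    genome_bp: int

    @property
    def percent(self) -> float:
        return 100.0 * self.shared_bp / self.genome_bp


# ---------------------------------------------------------------------------
# circular canonicalization
# ---------------------------------------------------------------------------

def canonicalize_circular(blocks: Sequence[int]) -> Tuple[int, ...]:
    """Rotate (and reflect if needed) a circular signed order so +1 leads.

    A circular molecule is invariant under rotation and under reflection
    (reverse the order and flip every sign); the canonical representative
    starts with +1.
    """
    b = list(blocks)
    if -1 in b:
        b = [-x for x in reversed(b)]
    i = b.index(1)
    return tuple(b[i:] + b[:i])


# ---------------------------------------------------------------------------
# Hannenhalli–Pevzner distance for linear signed permutations
# ---------------------------------------------------------------------------

def linear_inversion_distance(perm: Sequence[int]) -> int:
    """Exact reversal distance of a linear signed permutation to identity.

    d = (n + 1) - c + h + f with c breakpoint-graph cycles, h hurdles and
    f the fortress indicator. O(n^2), ample for block counts seen here.
    """
    n = len(perm)
    if n == 0:
        return 0
    if sorted(abs(x) for x in perm) != list(range(1, n + 1)):
        raise ValueError("not a signed permutation of 1..n")

    # doubled representation framed by 0 and 2n+1
    s = [0]
    for x in perm:
        if x > 0:
            s.extend((2 * x - 1, 2 * x))
        else:
            s.extend((-2 * x, -2 * x - 1))
    s.append(2 * n + 1)

    pos = [0] * (2 * n + 2)
    for i, v in enumerate(s):
        pos[v] = i

    # black edges pair positions (2i, 2i+1); gray edges pair values (2i, 2i+1)
    n_black = n + 1
    visited = [False] * (2 * n + 2)
    cycles: List[List[int]] = []  # each cycle = list of gray edge ids i (edge 2i--2i+1)
    for start in range(0, 2 * n + 2, 2):
        if visited[start]:
            continue
        cyc_gray: List[int] = []
        p = start  # position
        while not visited[p]:
            visited[p] = True
            q = p + 1 if p % 2 == 0 else p - 1  # black edge partner position
            visited[q] = True
            v = s[q]
            w = v + 1 if v % 2 == 0 else v - 1  # gray edge partner value
            cyc_gray.append(min(v, w) // 2)
            p = pos[w]
        cycles.append(cyc_gray)

    c = len(cycles)
    d0 = n_black - c
    nontrivial = [cy for cy in cycles if len(cy) > 1]
    if not nontrivial:
        return d0

    # gray edge i connects values 2i and 2i+1; oriented iff endpoint positions
    # share parity
    def gray_positions(i: int) -> Tuple[int, int]:
        a, b = pos[2 * i], pos[2 * i + 1]
        return (a, b) if a < b else (b, a)

    def edge_oriented(i: int) -> bool:
        a, b = gray_positions(i)
        return (b - a) % 2 == 0

    # interleaving graph over nontrivial cycles -> components
    m = len(nontrivial)
    spans = []
    for cy in nontrivial:
        ivs = [gray_positions(g) for g in cy]
        spans.append(ivs)

    def interleave(i: int, j: int) -> bool:
        for (a, b) in spans[i]:
            for (cc, dd) in spans[j]:
                if (a < cc < b < dd) or (cc < a < dd < b):
                    return True
        return False

    comp = list(range(m))

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            if find(i) != find(j) and interleave(i, j):
                comp[find(i)] = find(j)

    comp_of_cycle = [find(i) for i in range(m)]
    comp_ids = set(comp_of_cycle)

    comp_oriented: Dict[int, bool] = {cid: False for cid in comp_ids}
    for idx, cy in enumerate(nontrivial):
        if any(edge_oriented(g) for g in cy):
            comp_oriented[comp_of_cycle[idx]] = True

    unoriented = [cid for cid in comp_ids if not comp_oriented[cid]]
    if not unoriented:
        return d0

    # label every position covered by an unoriented component's gray edges,
    # scan the (circular) position line, collapse runs; a component whose
    # label forms exactly one circular run is a hurdle.
    label = [-1] * (2 * n + 2)
    for idx, cy in enumerate(nontrivial):
        cid = comp_of_cycle[idx]
        if comp_oriented[cid]:
            continue
        for g in cy:
            a, b = gray_positions(g)
            label[a] = cid
            label[b] = cid
    seq = [l for l in label if l != -1]
    runs: List[int] = []
    for l in seq:
        if not runs or runs[-1] != l:
            runs.append(l)
    if len(runs) > 1 and runs[0] == runs[-1]:
        runs = runs[1:]  # circular collapse

    counts: Dict[int, int] = {}
    for r in runs:
        counts[r] = counts.get(r, 0) + 1
    hurdles = [cid for cid in unoriented if counts.get(cid, 0) == 1]
    h = len(hurdles)
    if h == 0:
        # unoriented components exist but none is a hurdle cannot happen:
        # a minimal unoriented component always forms one run
        raise AssertionError("unoriented components without hurdles")

    f = 0
    if h % 2 == 1:
        def is_superhurdle(cid: int) -> bool:
            # removing cid must turn some non-hurdle unoriented component
            # into a hurdle: its single run is flanked circularly by the
            # same component which occurs exactly twice
            k = len(runs)
            if k < 3:
                return False
            i = runs.index(cid)
            left = runs[(i - 1) % k]
            right = runs[(i + 1) % k]
            return left == right and counts.get(left, 0) == 2

        if all(is_superhurdle(cid) for cid in hurdles):
            f = 1

    return d0 + h + f


def inversion_distance(perm: SignedPermutation | Sequence[int]) -> int:
    """Minimum number of inversions sorting a circular signed order to identity.

    The circular problem reduces to a linear one: rotate/reflect so block 1
    leads as +1, drop it, and relabel the remaining blocks 2..n down to
    1..n-1; the linear reversal distance of that permutation is the circular
    inversion distance.
    """
    blocks = perm.blocks if isinstance(perm, SignedPermutation) else tuple(perm)
    if isinstance(perm, Sequence) and not isinstance(perm, SignedPermutation):
        SignedPermutation(tuple(blocks))  # validate
    canon = canonicalize_circular(blocks)
    rest = [(x - 1) if x > 0 else (x + 1) for x in canon[1:]]
    return linear_inversion_distance(rest)


# ---------------------------------------------------------------------------
# block construction from shared unique anchors
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _unique_kmer_index(seq: str, k: int) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    L = len(seq)
    ext = seq + seq[: k - 1]  # circular k-mers
    for i in range(L):
        km = ext[i : i + k]
        counts[km] = counts.get(km, 0) + 1
    return {ext[i : i + k]: i for i in range(L) if counts[ext[i : i + k]] == 1}


def blocks_from_anchors(
    genome_a: str,
    genome_b: str,
    k: int = 21,
    min_block: int = 500,
    genome_id_b: str = "B",
    max_gap: int = 2000,
) -> Tuple[SignedPermutation, SharedFraction]:
    """Derive B's signed block order relative to A from shared unique k-mers.

    Unique k-mers present in both circular genomes (either strand of B) are
    chained along A into maximal collinear, consistently stranded runs; runs
    spanning at least ``min_block`` bp become numbered blocks 1..n along A,
    and B's order and strand of those blocks is the signed permutation.
    A simplified stand-in for whole-genome collinear-block alignment, meant
    for genomes that share long exactly conserved tracts.
    """
    idx_a = _unique_kmer_index(genome_a, k)
    idx_bf = _unique_kmer_index(genome_b, k)
    rc_b = _revcomp(genome_b)
    idx_br = _unique_kmer_index(rc_b, k)
    Lb = len(genome_b)

    anchors: List[Tuple[int, int, int]] = []  # (posA, posB_forwardcoords, strand)
    for km, pa in idx_a.items():
        if km in idx_bf and km not in idx_br:
            anchors.append((pa, idx_bf[km], +1))
        elif km in idx_br and km not in idx_bf:
            # position of k-mer start on forward strand of B
            pb = Lb - k - idx_br[km]
            anchors.append((pa, pb, -1))
    if not anchors:
        raise ValueError("no homology detected: no shared unique anchors")

    anchors.sort()
    # chain along A: same strand, consistent diagonal, bounded gap
    runs: List[List[Tuple[int, int, int]]] = [[anchors[0]]]
    for a in anchors[1:]:
        pa, pb, st = a
        qa, qb, qt = runs[-1][-1]
        da = pa - qa
        db = (pb - qb) * st
        same = (
            st == qt
            and 0 < da <= max_gap
            and abs(db - da) <= 20
        )
        if same:
            runs[-1].append(a)
        else:
            runs.append([a])

    blocks = []
    for run in runs:
        span = run[-1][0] + k - run[0][0]
        if span >= min_block:
            blocks.append(run)
    if not blocks:
        raise ValueError("no homology detected: no block reaches min_block")

    shared = sum(r[-1][0] + k - r[0][0] for r in blocks)
    # number blocks 1..n along A; order them along B
    order = []
    for i, run in enumerate(blocks, start=1):
        st = run[0][2]
        bpos = min(run[0][1], run[-1][1])
        order.append((bpos, i * st))
    order.sort()
    perm = SignedPermutation(tuple(sig for _, sig in order), genome_id=genome_id_b)
    return perm, SharedFraction(shared_bp=shared, genome_bp=len(genome_a))


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def pairwise_rate(events: int, divergence_time_mya: float) -> RateEstimate:
    """Pairwise rearrangement rate: events divided by double the divergence time."""
    if divergence_time_mya <= 0:
        raise ValueError("divergence time must be > 0 Mya")
    if events < 0:
        raise ValueError("events must be >= 0")
    return RateEstimate(events, divergence_time_mya, "pairwise", events / (2.0 * divergence_time_mya))


def branch_rate(events: int, branch_time_mya: float) -> RateEstimate:
    """Per-branch rearrangement rate: events divided by the branch's absolute time."""
    if branch_time_mya <= 0:
        raise ValueError("branch time must be > 0 Mya")
    if events < 0:
        raise ValueError("events must be >= 0")
    return RateEstimate(events, branch_time_mya, "branch", events / branch_time_mya)


def tree_rates(tree, node_orders: Dict[str, SignedPermutation]) -> List[Dict]:
    """Per-branch rearrangement events and rates on a dated tree.

    ``tree`` is a dendropy Tree with branch lengths in Mya; ``node_orders``
    maps node labels (taxon labels for leaves, node labels for internals) to
    signed block orders over a shared block set. Events on a branch are the
    inversion distance between parent and child orders.
    """
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        def _label(nd):
            if nd.taxon is not None and nd.taxon.label:
                return nd.taxon.label
            return nd.label
        child_l, parent_l = _label(node), _label(node.parent_node)
        for lab in (parent_l, child_l):
            if lab not in node_orders:
                raise KeyError(f"missing block order for tree node {lab!r}")
        parent = node_orders[parent_l]
        child = node_orders[child_l]
        events = relative_distance(parent, child)
        t = node.edge.length
        if t is None or t <= 0:
            raise ValueError(f"branch above {child_l!r} has no positive length")
        out.append(
            {
                "parent": parent_l,
                "child": child_l,
                "events": events,
                "time_mya": t,
                "rate": branch_rate(events, t).rate,
            }
        )
    return out


def relative_distance(a: SignedPermutation, b: SignedPermutation) -> int:
    """Inversion distance between two circular orders over the same block set."""
    if a.n != b.n:
        raise ValueError("block sets differ in size")
    # express b in the coordinate frame where a is the identity
    posneg = {}
    for i, x in enumerate(a.blocks, start=1):
        posneg[abs(x)] = (i, 1 if x > 0 else -1)
    rel = []
    for x in b.blocks:
        i, s = posneg[abs(x)]
        rel.append(i * s * (1 if x > 0 else -1))
    return inversion_distance(SignedPermutation(tuple(rel)))
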