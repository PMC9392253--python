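"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools
from collections import deque
from typing import Dict, Iterable, Tuple

import numpy as np
import pytest

from mitostructkit.rearrangement import canonicalize_circular
from mitostructkit.simulate import SimulationConfig, gen_circular_genome


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations they check)
# ---------------------------------------------------------------------------

def circular_inversion_moves(p: Tuple[int, ...]) -> Iterable[Tuple[int, ...]]:
    """All canonical states one circular-arc inversion away from p."""
    n = len(p)
    for start in range(n):
        for length in range(1, n):
            q = list(p)
            idx = [(start + i) % n for i in range(length)]
            seg = [-q[i] for i in reversed(idx)]
            for i, v in zip(idx, seg):
                q[i] = v
            yield canonicalize_circular(q)


def circular_bfs_distances(n: int) -> Dict[Tuple[int, ...], int]:
    """Exact inversion distances for every circular signed permutation of n."""
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    dq = deque([ident])
    while dq:
        p = dq.popleft()
        for q in circular_inversion_moves(p):
            if q not in dist:
                dist[q] = dist[p] + 1
                dq.append(q)
    return dist


def bounded_bfs_distance(target: Tuple[int, ...], max_depth: int) -> int | None:
    """BFS distance from circular identity to target, or None if > max_depth."""
    n = len(target)
    target = canonicalize_circular(target)
    frontier = {tuple(range(1, n + 1))}
    seen = set(frontier)
    for d in range(max_depth + 1):
        if target in frontier:
            return d
        nxt = set()
        for p in frontier:
            for q in circular_inversion_moves(p):
                if q not in seen:
                    seen.add(q)
                    nxt.add(q)
        frontier = nxt
    return None


def all_circular_signed_perms(n: int) -> Iterable[Tuple[int, ...]]:
    """Every canonical circular signed permutation of 1..n (starts with +1)."""
    for rest in itertools.permutations(range(2, n + 1)):
        for signs in itertools.product((1, -1), repeat=n - 1):
            yield (1,) + tuple(s * x for s, x in zip(signs, rest))


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form Pearson chi-square for a 2x2 table [[a,b],[c,d]]."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_genome():
    """20-kb genome with one long direct pair and one medium pair."""
    cfg = SimulationConfig(
        seed=42, genome_length=20_000, repeat_spec=((2000, 100.0, 1), (300, 100.0, 1))
    )
    genome, truth = gen_circular_genome(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def default_genome():
    cfg = SimulationConfig(seed=0)
    genome, truth = gen_circular_genome(cfg)
    return cfg, genome, truth
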