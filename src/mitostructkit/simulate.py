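"""Synthetic data with known ground truth for every analysis stage.

Generates circular genomes with planted repeat pairs, long reads drawn from
mixtures of the reference and recombinant genome conformations, scrambled
signed block orders, two-population haplotype matrices with planted sweep
windows, and depth-ratio profiles drawn from the empirical low/high bands.
Every generator is a pure function of its seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .rearrangement import SignedPermutation, canonicalize_circular
from .repeats import RepeatPair
from .sequences import CircularSequence, revcomp

__all__ = [
    "SimulationConfig",
    "SimulatedRead",
    "gen_circular_genome",
    "sim_long_reads",
    "gen_rearranged_pair",
    "gen_population_variants",
    "gen_depth_profiles",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Desk-scale defaults: a 50-kb circular genome (real Rosaceae mitogenomes
    run 278-536 kb; everything here scales linearly), post-correction long
    reads with 0.5% residual substitution error, and the empirical
    depth-ratio bands low (0.24-0.72) / high (6.94-142.98).
    """

    seed: int = 0
    genome_length: int = 50_000
    # (length bp, identity %, count) or (length, identity, count, orientation)
    repeat_spec: Tuple = ((2000, 100.0, 1), (600, 100.0, 1), (300, 100.0, 2), (80, 100.0, 3))
    read_error_rate: float = 0.005
    read_length_mean: int = 6000
    read_length_sd: int = 2000
    coverage: float = 40.0
    recomb_fraction: float = 0.3
    n_inversions: int = 3
    pop_sizes: Tuple[int, int] = (33, 52)
    # (start bp, end bp, diversity_reduction fold, divergence boost)
    sweep_windows: Tuple = ((20_000, 25_000, 10.0, 1.0),)
    snp_density: float = 0.02
    missing_rate: float = 0.02
    depth_bands: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (0.24, 0.72),
        (6.94, 142.98),
    )

    def __post_init__(self) -> None:
        for name in ("read_error_rate", "recomb_fraction", "missing_rate", "snp_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        (lo1, lo2), (hi1, hi2) = self.depth_bands
        if not (lo1 < lo2 < hi1 < hi2):
            raise ValueError("depth bands must be non-overlapping with low_max < high_min")
        if self.genome_length <= 0 or self.coverage < 0:
            raise ValueError("genome_length and coverage must be positive")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs <= 0:
        return seq
    arr = bytearray(seq, "ascii")
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for p in pos:
        alt = [b for b in b"ACGT" if b != arr[p]]
        arr[p] = alt[rng.integers(0, 3)]
    return arr.decode("ascii")


# ---------------------------------------------------------------------------
# circular genome with planted repeats
# ---------------------------------------------------------------------------

def gen_circular_genome(cfg: SimulationConfig) -> Tuple[CircularSequence, List[RepeatPair]]:
    """A circular genome containing exactly the configured repeat pairs.

    Background sequence is i.i.d. uniform ACGT, rejection-checked so that no
    non-planted exact repeat of 50 bp or more exists. Copies of each pair
    are separated by at least 500 bp of unique sequence.
    """
    spec = []
    for entry in cfg.repeat_spec:
        if len(entry) == 3:
            length, identity, count = entry
            orient = "direct"
        else:
            length, identity, count, orient = entry
        if length > cfg.genome_length // 2 - 1000:
            raise ValueError("genome_length must be >= 2*(max repeat length + 1000)")
        for _ in range(int(count)):
            spec.append((int(length), float(identity), orient))

    n_copies = 2 * len(spec)
    min_gap = 500
    unique_total = cfg.genome_length - sum(2 * l for l, _, _ in spec)
    if n_copies and unique_total < min_gap * n_copies:
        raise ValueError(
            "infeasible packing: requested repeats plus 500-bp separations exceed genome length"
        )

    rng = _rng(cfg.seed, 1)
    for _attempt in range(20):
        # lay out copies around the circle with random unique gaps >= 500 bp
        units = []
        for length, identity, orient in spec:
            unit = _random_seq(rng, length)
            n_subs = int(round(length * (1.0 - identity / 100.0)))
            other = _mutate(rng, unit, n_subs)
            if orient == "inverted":
                other = revcomp(other)
            units.append((unit, other, identity, orient, length))

        slots = []
        for i, u in enumerate(units):
            slots.append((i, 0))
            slots.append((i, 1))
        order = rng.permutation(len(slots))
        slots = [slots[i] for i in order]

        if n_copies:
            extra = unique_total - min_gap * n_copies
            cuts = np.sort(rng.integers(0, extra + 1, size=n_copies - 1)) if n_copies > 1 else []
            parts = np.diff(np.concatenate(([0], cuts, [extra]))) if n_copies > 1 else [extra]
            gaps = [min_gap + int(p) for p in parts]
        else:
            gaps = []

        seq_parts: List[str] = []
        coords: Dict[Tuple[int, int], Tuple[int, int]] = {}
        pos = 0
        for slot, gap in zip(slots, gaps):
            g = _random_seq(rng, gap)
            seq_parts.append(g)
            pos += gap
            i, which = slot
            unit, other, identity, orient, length = units[i]
            copy_seq = unit if which == 0 else other
            seq_parts.append(copy_seq)
            coords[(i, which)] = (pos, pos + length)
            pos += length
        if not n_copies:
            seq_parts.append(_random_seq(rng, cfg.genome_length))
        seq = "".join(seq_parts)
        assert len(seq) == cfg.genome_length

        truth: List[RepeatPair] = []
        for i, (unit, other, identity, orient, length) in enumerate(units):
            a = coords[(i, 0)]
            b = coords[(i, 1)]
            if a[0] > b[0]:
                a, b = b, a
            truth.append(RepeatPair(a, b, length, identity, orient))

        # make each planted repeat a maximal exact match: force the bases
        # flanking copy B to mismatch the aligned bases flanking copy A, so
        # chance extension past the recorded boundaries is impossible
        seq = _pin_boundaries(seq, truth)

        if _no_accidental_repeats(seq, truth, k=50):
            genome = CircularSequence(
                id=f"synthetic_mito_seed{cfg.seed}", seq=seq, features={"repeats": truth}
            )
            return genome, truth
    raise RuntimeError("failed to generate a clean background after 20 attempts")


_SHIFT = {65: 67, 67: 71, 71: 84, 84: 65}  # A->C->G->T->A, always a mismatch
_COMPL = {65: 84, 84: 65, 67: 71, 71: 67}


def _pin_boundaries(seq: str, truth: Sequence[RepeatPair], pad: int = 16) -> str:
    """Force the ``pad`` bases flanking copy B to mismatch copy A's flanks.

    For a direct pair the aligned partner of base e2+j is e1+j (and s2-1-j
    pairs with s1-1-j); for an inverted pair the alignment continues onto
    the complementary strand. Guarantees the planted coordinates are the
    maximal exact match, so truth boundaries are exact.
    """
    arr = bytearray(seq, "ascii")
    L = len(arr)
    for p in truth:
        (s1, e1), (s2, e2) = p.locusA, p.locusB
        for j in range(pad):
            if p.orientation == "direct":
                arr[(s2 - 1 - j) % L] = _SHIFT[arr[(s1 - 1 - j) % L]]
                arr[(e2 + j) % L] = _SHIFT[arr[(e1 + j) % L]]
            else:
                # upstream of A aligns with rc(downstream of B) and v.v.
                arr[(e2 + j) % L] = _SHIFT[_COMPL[arr[(s1 - 1 - j) % L]]]
                arr[(s2 - 1 - j) % L] = _SHIFT[_COMPL[arr[(e1 + j) % L]]]
    return arr.decode("ascii")


def _no_accidental_repeats(seq: str, truth: Sequence[RepeatPair], k: int) -> bool:
    """No exact k-mer occurs twice outside the planted repeat copies."""
    L = len(seq)
    planted = np.zeros(L, dtype=bool)
    for p in truth:
        for s, e in (p.locusA, p.locusB):
            planted[s % L : min(e, L)] = True
    ext = seq + seq[: k - 1]
    seen: Dict[str, int] = {}
    for i in range(L):
        if planted[i : i + k].all() if i + k <= L else True:
            continue
        km = ext[i : i + k]
        if km in seen:
            return False
        seen[km] = i
    return True


# ---------------------------------------------------------------------------
# long reads from conformation mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedRead:
    id: str
    seq: str
    label: str  # "reference" | "recombinant"
    conformation: str


def _recombinant_circles(genome: CircularSequence, pair: RepeatPair) -> List[Tuple[str, str]]:
    """Circular sequences of the recombinant conformation(s) for one pair.

    Crossover is taken at the repeat midpoint (exact pairs are unaffected).
    A direct pair splits the circle into two subcircles; an inverted pair
    inverts the segment between the copies.
    """
    seq = genome.seq
    L = len(seq)
    (s1, e1), (s2, e2) = pair.locusA, pair.locusB
    if e1 > L or e2 > L:
        rot = (e2 % L) if e2 > L else (e1 % L)  # rotate so no copy wraps
        g = genome.rotate(rot)
        p = _shift_pair(pair, -rot, L)
        return _recombinant_circles(g, p)
    if pair.orientation == "direct":
        mid1 = (s1 + e1) // 2
        mid2 = (s2 + e2) // 2
        # crossover joins copy1's first half to copy2's second half and v.v.
        c1 = seq[mid1:mid2]  # circle carrying junction (up1)-repeat-(down2)? see below
        c2 = seq[mid2:] + seq[:mid1]
        return [("recomb_circle1", c1), ("recomb_circle2", c2)]
    # inverted: flip the intervening segment
    q = seq[:e1] + revcomp(seq[e1:s2]) + seq[s2:]
    return [("recomb_inverted", q)]


def _shift_pair(pair: RepeatPair, shift: int, L: int) -> RepeatPair:
    a = ((pair.locusA[0] + shift) % L, (pair.locusA[0] + shift) % L + pair.length)
    b = ((pair.locusB[0] + shift) % L, (pair.locusB[0] + shift) % L + pair.length)
    if a[0] > b[0]:
        a, b = b, a
    return RepeatPair(a, b, pair.length, pair.identity, pair.orientation)


def sim_long_reads(
    genome: CircularSequence,
    pair: RepeatPair,
    cfg: SimulationConfig,
    n_reads: Optional[int] = None,
) -> List[SimulatedRead]:
    """Long reads from a mixture of reference and recombinant conformations.

    A fraction ``cfg.recomb_fraction`` of reads is drawn (binomially) from
    the recombinant conformation(s) of ``pair``, the rest from the reference
    circle. Read starts are uniform over the (circular) source molecule,
    lengths are lognormal truncated to [500, 4*mean], strands are random and
    substitution errors are i.i.d. at ``cfg.read_error_rate``.
    """
    if cfg.read_length_mean < pair.length + 400:
        warnings.warn(
            "read_length_mean < repeat length + 400: reads cannot span the repeat "
            "plus both 200-bp flanks; the recombination assay will be powerless",
            stacklevel=2,
        )
    rng = _rng(cfg.seed, 2)
    L = len(genome)
    if n_reads is None:
        n_reads = int(round(cfg.coverage * L / cfg.read_length_mean))
    n_recomb = int(rng.binomial(n_reads, cfg.recomb_fraction))

    circles = [("reference", genome.seq)]
    recombs = _recombinant_circles(genome, pair)

    mu = math.log(cfg.read_length_mean**2 / math.sqrt(cfg.read_length_mean**2 + cfg.read_length_sd**2))
    sigma = math.sqrt(math.log(1 + (cfg.read_length_sd / cfg.read_length_mean) ** 2))

    def draw_len() -> int:
        x = int(rng.lognormal(mu, sigma))
        return max(500, min(x, 4 * cfg.read_length_mean))

    def draw_read(source: List[Tuple[str, str]], label: str, idx: int) -> SimulatedRead:
        lens = np.array([len(s) for _, s in source], dtype=float)
        ci = rng.choice(len(source), p=lens / lens.sum()) if len(source) > 1 else 0
        name, circ = source[ci]
        n = len(circ)
        rl = min(draw_len(), n)
        start = int(rng.integers(0, n))
        read = (circ + circ)[start : start + rl]
        if rng.random() < 0.5:
            read = revcomp(read)
        n_err = rng.binomial(rl, cfg.read_error_rate)
        read = _mutate(rng, read, int(n_err))
        return SimulatedRead(id=f"read{idx:06d}_{label}", seq=read, label=label, conformation=name)

    reads: List[SimulatedRead] = []
    labels = np.zeros(n_reads, dtype=bool)
    labels[:n_recomb] = True
    rng.shuffle(labels)
    for i, is_rec in enumerate(labels):
        if is_rec:
            reads.append(draw_read(recombs, "recombinant", i))
        else:
            reads.append(draw_read(circles, "reference", i))
    return reads


# ---------------------------------------------------------------------------
# scrambled block orders
# ---------------------------------------------------------------------------

def gen_rearranged_pair(
    n_blocks: int, k: int, seed: int = 0
) -> Tuple[SignedPermutation, SignedPermutation, int]:
    """Identity and a copy scrambled by k uniformly random circular inversions."""
    if n_blocks < 3:
        raise ValueError("n_blocks must be >= 3")
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = _rng(seed, 3)
    blocks = list(range(1, n_blocks + 1))
    for _ in range(k):
        start = int(rng.integers(0, n_blocks))
        length = int(rng.integers(1, n_blocks))  # proper arc of the circle
        idx = [(start + i) % n_blocks for i in range(length)]
        seg = [-blocks[i] for i in reversed(idx)]
        for i, v in zip(idx, seg):
            blocks[i] = v
    ident = SignedPermutation(tuple(range(1, n_blocks + 1)), genome_id="identity")
    scrambled = SignedPermutation(canonicalize_circular(blocks), genome_id=f"scrambled_k{k}")
    return ident, scrambled, k


# ---------------------------------------------------------------------------
# two-population haplotype matrices with planted sweeps
# ---------------------------------------------------------------------------

def gen_population_variants(cfg: SimulationConfig):
    """Haploid wild/cultivated variant matrix with planted sweep windows.

    Neutral sites share one allele frequency across populations; inside a
    sweep window the cultivated-population frequency is pushed toward the
    nearest fixation point by (diversity_reduction * divergence_boost),
    reducing cultivated diversity and raising differentiation. Missing
    calls are i.i.d. Returns (VariantMatrix, sweep truth windows).
    """
    from .popgen import VariantMatrix  # local import to avoid a cycle

    n_wild, n_cul = cfg.pop_sizes
    if n_wild < 8 or n_cul < 8:
        raise ValueError("pop_sizes must be >= (8, 8) haplotypes for stable estimators")
    rng = _rng(cfg.seed, 4)
    L = cfg.genome_length
    is_var = rng.random(L) < cfg.snp_density
    positions = np.nonzero(is_var)[0] + 1  # 1-based
    m = len(positions)
    p = np.clip(rng.beta(0.5, 0.5, size=m), 0.05, 0.95)

    q = p.copy()
    for (ws, we, reduction, boost) in cfg.sweep_windows:
        inside = (positions > ws) & (positions <= we)
        factor = float(reduction) * float(boost)
        lower = p[inside] < 0.5
        q_in = np.where(lower, p[inside] / factor, 1.0 - (1.0 - p[inside]) / factor)
        q[inside] = q_in

    gt_wild = (rng.random((m, n_wild)) < p[:, None]).astype(np.int8)
    gt_cul = (rng.random((m, n_cul)) < q[:, None]).astype(np.int8)
    gt = np.concatenate([gt_wild, gt_cul], axis=1)
    miss = rng.random(gt.shape) < cfg.missing_rate
    gt[miss] = -1

    samples = [f"W{i:03d}" for i in range(n_wild)] + [f"C{i:03d}" for i in range(n_cul)]
    pops = {s: ("wild" if s.startswith("W") else "cultivated") for s in samples}
    vm = VariantMatrix(
        samples=samples,
        populations=pops,
        positions=positions.astype(np.int64),
        genotypes=gt,
        reference_length=L,
    )
    truth = [(int(ws), int(we)) for (ws, we, _, _) in cfg.sweep_windows]
    return vm, truth


# ---------------------------------------------------------------------------
# depth-ratio profiles
# ---------------------------------------------------------------------------

def gen_depth_profiles(
    cfg: SimulationConfig,
    n_samples: int,
    presence_truth: Sequence[bool],
    region: Tuple[int, int] = (0, 5000),
) -> pd.DataFrame:
    """Per-sample region/whole-genome depths from the low/high ratio bands.

    Present samples draw their true ratio uniformly from the high band,
    absent samples from the low band; observed depths carry Poisson noise.
    """
    if len(presence_truth) != n_samples:
        raise ValueError("presence_truth must have one entry per sample")
    rng = _rng(cfg.seed, 5)
    (lo1, lo2), (hi1, hi2) = cfg.depth_bands
    rows = []
    for i, present in enumerate(presence_truth):
        wdep_true = rng.uniform(20.0, 60.0)
        ratio_true = rng.uniform(hi1, hi2) if present else rng.uniform(lo1, lo2)
        wdep = rng.poisson(wdep_true)
        idep = rng.poisson(ratio_true * wdep_true)
        rows.append(
            {
                "sample_id": f"S{i:03d}",
                "region_start": region[0],
                "region_end": region[1],
                "Idep": float(idep),
                "Wdep": float(wdep),
                "ratio_true": ratio_true,
                "present_true": bool(present),
            }
        )
    return pd.DataFrame(rows)
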