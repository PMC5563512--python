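"""Design of hairpin stems with full k-mer coverage and a flat landscape.

A selectivity hairpin must present every binding motif of length K at least
once and not more than twice, so that blockage statistics are unbiased, and
its unzipping free-energy landscape must be as flat as possible so that the
only roadblocks are ligand-induced.  Because a hairpin duplex carries both
strands, a window and its reverse complement probe the same duplex motif;
with this equivalence the 256 tetramers collapse to 136 classes (16 of the
256 are reverse-complement palindromes), which fit into a 170-bp stem
(167 windows, 31 of them second occurrences).

The designer first builds a valid covering sequence by a randomized greedy
walk on the (K-1)-mer overlap graph with backtracking, then minimizes the
landscape roughness R by Metropolis Monte Carlo with geometric cooling.
One-base substitutions (re-checked against the coverage constraint) are
mixed with two rearrangements that conserve the window multiset exactly:
excising the closed sub-walk between two occurrences of the same (K-1)-mer
and splicing it at another occurrence, and reverse-complementing in place a
segment flanked by reverse-complementary (K-1)-mers (counts are preserved
under duplex class counting).  An optional polish stage descends directly
on the largest forward rise of the cumulative step-energy profile, the
quantity that sets the unzipping barrier at coexistence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .energy_model import (
    HairpinSequence,
    NNModel,
    reverse_complement,
    roughness_of_profile,
    step_energy_profile,
)

__all__ = [
    "DesignSpec",
    "CoverageReport",
    "kmer_class_count",
    "kmer_class",
    "coverage",
    "minimal_feasible_length",
    "initial_valid_sequence",
    "design_sequence",
]

_BASES = "ACGT"


@dataclass
class DesignSpec:
    """Design problem: motif length K, stem length N, annealing schedule."""

    K: int = 4
    N: int = 170
    seed: int = 0
    initial_temperature: float = 50.0
    cooling_factor: float = 0.9995
    steps: int = 12000
    rc_equivalence: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")


@dataclass
class CoverageReport:
    """Occurrence count of every k-mer class over the stem's windows."""

    counts: dict[str, int]
    K: int
    rc_equivalence: bool
    satisfied: bool = field(init=False)

    def __post_init__(self) -> None:
        self.satisfied = all(1 <= c <= 2 for c in self.counts.values())


def kmer_class(kmer: str, rc_equivalence: bool = True) -> str:
    """Canonical representative of a k-mer (lexicographic min with its rc)."""
    if not rc_equivalence:
        return kmer
    return min(kmer, reverse_complement(kmer))


def kmer_class_count(K: int, rc_equivalence: bool = True) -> int:
    """Number of distinct k-mer classes: 4^K, or (4^K + P)/2 with duplex
    (reverse-complement) equivalence, P = number of rc-palindromes."""
    if K < 1:
        raise ValueError("K must be >= 1")
    total = 4**K
    if not rc_equivalence:
        return total
    palindromes = 0 if K % 2 else 4 ** (K // 2)
    return (total + palindromes) // 2


def minimal_feasible_length(K: int, rc_equivalence: bool = True) -> int:
    """Lower bound on stem length: one window per class plus the K-1 overhang."""
    return kmer_class_count(K, rc_equivalence) + K - 1


def maximal_feasible_length(K: int, rc_equivalence: bool = True) -> int:
    """Upper bound: at most two windows per class plus the K-1 overhang."""
    return 2 * kmer_class_count(K, rc_equivalence) + K - 1


def _check_feasible(spec: DesignSpec) -> None:
    lo = minimal_feasible_length(spec.K, spec.rc_equivalence)
    hi = maximal_feasible_length(spec.K, spec.rc_equivalence)
    if not lo <= spec.N <= hi:
        raise ValueError(
            f"N={spec.N} infeasible for K={spec.K} "
            f"({kmer_class_count(spec.K, spec.rc_equivalence)} classes, each needed "
            f"once or twice): N must lie in [{lo}, {hi}]"
        )


def coverage(seq: HairpinSequence | str, spec: DesignSpec) -> CoverageReport:
    """Count occurrences of every k-mer class over all N-K+1 windows."""
    stem = seq.stem if isinstance(seq, HairpinSequence) else seq
    counts = {
        kmer_class("".join(p), spec.rc_equivalence): 0
        for p in itertools.product(_BASES, repeat=spec.K)
    }
    for i in range(len(stem) - spec.K + 1):
        counts[kmer_class(stem[i : i + spec.K], spec.rc_equivalence)] += 1
    return CoverageReport(counts=counts, K=spec.K, rc_equivalence=spec.rc_equivalence)


def _counts_of(stem: str, K: int, rc: bool) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(stem) - K + 1):
        c = kmer_class(stem[i : i + K], rc)
        counts[c] = counts.get(c, 0) + 1
    return counts


def _counts_valid(stem: str, K: int, rc: bool, n_classes: int) -> bool:
    counts = _counts_of(stem, K, rc)
    return len(counts) == n_classes and all(1 <= c <= 2 for c in counts.values())


def initial_valid_sequence(
    spec: DesignSpec,
    nn: NNModel | None = None,
    max_restarts: int = 2000,
) -> HairpinSequence:
    """Build a stem of length N whose windows cover every k-mer class 1-2 times.

    Randomized greedy walk: extend one base at a time, never letting any class
    exceed two occurrences, preferring bases that cover a class not yet seen;
    limited backtracking on dead ends, full restarts otherwise.
    """
    _check_feasible(spec)
    rng = np.random.default_rng(spec.seed)
    K, N, rc = spec.K, spec.N, spec.rc_equivalence
    n_classes = kmer_class_count(K, rc)

    for _ in range(max_restarts):
        stem = "".join(rng.choice(list(_BASES), size=K - 1)) if K > 1 else ""
        counts: dict[str, int] = {}
        history: list[str] = []  # class credited per appended base
        dead = False
        backtracks = 0
        while len(stem) < N:
            fresh, allowed = [], []
            for b in _BASES:
                cand = (stem[-(K - 1) :] if K > 1 else "") + b
                cls = kmer_class(cand, rc)
                c = counts.get(cls, 0)
                if c >= 2:
                    continue
                (fresh if c == 0 else allowed).append((b, cls))
            pool = fresh if fresh else allowed
            if not pool:
                if history and backtracks < 4 * N:
                    cls = history.pop()
                    stem = stem[:-1]
                    counts[cls] -= 1
                    backtracks += 1
                    continue
                dead = True
                break
            b, cls = pool[rng.integers(len(pool))]
            stem += b
            counts[cls] = counts.get(cls, 0) + 1
            history.append(cls)
        if dead or len(stem) < N:
            continue
        if len(counts) == n_classes and all(1 <= c <= 2 for c in counts.values()):
            return HairpinSequence(stem)
    raise RuntimeError(
        f"no valid covering sequence found for K={spec.K}, N={spec.N} "
        f"after {max_restarts} restarts"
    )


def _overlap_index(stem: str, m: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(stem) - m + 1):
        idx.setdefault(stem[i : i + m], []).append(i)
    return idx


def _propose(stem: str, K: int, rc: bool, rng: np.random.Generator):
    """One move: substitution ('sub', pos, base) or a rearranged full stem."""
    m = max(K - 1, 1)
    kind = rng.random()
    if kind >= 0.9 or len(stem) <= m + 1:
        return ("sub", int(rng.integers(len(stem))), _BASES[int(rng.integers(4))])
    idx = _overlap_index(stem, m)
    if kind < 0.45:
        # excise the closed sub-walk between two occurrences of an m-mer and
        # splice it back at a (possibly different) occurrence
        multi = [k for k, v in idx.items() if len(v) >= 2]
        if not multi:
            return None
        mer = multi[int(rng.integers(len(multi)))]
        occ = idx[mer]
        a, b = sorted(rng.choice(len(occ), size=2, replace=False))
        i, j = occ[a], occ[b]
        seg = stem[i + m : j + m]
        if not seg:
            return None
        remainder = stem[: i + m] + stem[j + m :]
        sites = [p for p in range(len(remainder) - m + 1) if remainder[p : p + m] == mer]
        if not sites:
            return None
        k = sites[int(rng.integers(len(sites)))]
        return remainder[: k + m] + seg + remainder[k + m :]
    # reverse-complement flip of a segment flanked by rc m-mers; only valid
    # under duplex class counting
    if not rc:
        return None
    pairs = []
    for mer, occ in idx.items():
        occ2 = idx.get(reverse_complement(mer))
        if not occ2:
            continue
        for a in occ:
            for b in occ2:
                if b > a:
                    pairs.append((a, b))
    if not pairs:
        return None
    a, b = pairs[int(rng.integers(len(pairs)))]
    return stem[:a] + reverse_complement(stem[a : b + m]) + stem[b + m :]


def max_rise(alpha: np.ndarray) -> float:
    """Largest forward rise of the cumulative deviation of alpha from its
    mean ramp — the unzipping barrier the profile produces at coexistence."""
    dev = np.concatenate([[0.0], np.cumsum(np.asarray(alpha) - np.mean(alpha))])
    return float(max(np.max(dev[1:] - np.minimum.accumulate(dev)[:-1]), 0.0))


def design_sequence(
    spec: DesignSpec,
    nn: NNModel | None = None,
    polish_steps: int = 30000,
) -> tuple[HairpinSequence, np.ndarray]:
    """Monte-Carlo design of a flat covering sequence.

    Stage 1 anneals the landscape roughness R by Metropolis with geometric
    cooling (temperature 0 reduces to pure descent; ΔR = 0 accepted); stage 2
    (`polish_steps` > 0) greedily descends on the largest forward rise of the
    cumulative step-energy profile.  Moves that would violate the coverage
    constraint are rejected outright.  Returns the best sequence found and
    the R trajectory recorded at the start and after every accepted move.
    Identical seeds give identical output.
    """
    nn = nn or NNModel()
    rng = np.random.default_rng(spec.seed)
    seq = initial_valid_sequence(spec, nn)
    stem = seq.stem
    K, rc = spec.K, spec.rc_equivalence
    n_classes = kmer_class_count(K, rc)

    def r_of(s: str) -> float:
        return roughness_of_profile(step_energy_profile(HairpinSequence(s), nn))

    def rise_of(s: str) -> float:
        return max_rise(step_energy_profile(HairpinSequence(s), nn))

    def candidate(move):
        if move is None:
            return None
        if isinstance(move, tuple):
            _, pos, base = move
            if stem[pos] == base:
                return None
            cand = stem[:pos] + base + stem[pos + 1 :]
            if not _counts_valid(cand, K, rc, n_classes):
                return None
            return cand
        return move if len(move) == len(stem) else None

    r_current = r_of(stem)
    trajectory = [r_current]
    temperature = spec.initial_temperature
    r_best, stem_best = r_current, stem
    for _ in range(spec.steps):
        cand = candidate(_propose(stem, K, rc, rng))
        if cand is not None:
            r_new = r_of(cand)
            delta = r_new - r_current
            if delta <= 0 or (
                temperature > 0 and rng.random() < np.exp(-delta / temperature)
            ):
                stem, r_current = cand, r_new
                trajectory.append(r_current)
                if r_current < r_best:
                    r_best, stem_best = r_current, stem
        temperature *= spec.cooling_factor

    # basin hopping: reheat-quench rounds from the best state visited
    for _ in range(3):
        stem, r_current = stem_best, r_best
        reheat = max(spec.initial_temperature * 0.05, 1e-9)
        for _ in range(spec.steps // 4):
            cand = candidate(_propose(stem, K, rc, rng))
            if cand is None:
                continue
            r_new = r_of(cand)
            delta = r_new - r_current
            if delta <= 0 or rng.random() < np.exp(-delta / reheat):
                stem, r_current = cand, r_new
        for _ in range(min(spec.steps, 3000)):
            cand = candidate(_propose(stem, K, rc, rng))
            if cand is None:
                continue
            r_new = r_of(cand)
            if r_new <= r_current:
                stem, r_current = cand, r_new
        if r_current < r_best:
            r_best, stem_best = r_current, stem
            trajectory.append(r_current)

    stem = stem_best
    best_rise, best_stem = rise_of(stem), stem
    for _ in range(polish_steps):
        cand = candidate(_propose(stem, K, rc, rng))
        if cand is None:
            continue
        rise_new = rise_of(cand)
        if rise_new <= best_rise:
            stem, best_rise, best_stem = cand, rise_new, cand
            r_current = r_of(cand)
            trajectory.append(r_current)

    return HairpinSequence(best_stem), np.asarray(trajectory)
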