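"""Duplex thermodynamics, ssDNA elasticity and the unzipping free-energy landscape.

A DNA hairpin held under force at its two ends unzips sequentially from the
fork.  The free energy of the partially unzipped state with the first ``n``
base pairs open, at force ``F``, is referenced to the folded hairpin: opening
base pair ``i`` costs its duplex stability ``alpha_i`` and gains the
stretching free energy of the two released ssDNA nucleotides:

    G_F(n) = sum_{i<=n} alpha_i - n * 2 * g_ss(F)

The loop-formation free energy G_loop is a constant shared by every state
and cancels in all the differences the assay measures, so it does not enter
the landscape.  ``alpha_i`` is the nearest-neighbour stability of base pair
``i`` (kBT > 0)
and ``g_ss(F)`` the stretching free energy per released nucleotide under the
freely jointed chain (FJC) model.  The coexistence force F_c is the force at
which folded (n = 0) and fully open (n = N) states have equal free energy;
above F_c a hairpin with a flat landscape unzips cooperatively in one step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KBT_KCAL_MOL, KBT_PN_NM, T_REF

__all__ = [
    "NNModel",
    "SSDNAModel",
    "HairpinSequence",
    "Landscape",
    "step_energy_profile",
    "ssdna_extension",
    "ssdna_free_energy",
    "landscape",
    "coexistence_force",
    "max_barrier",
    "roughness",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Unified nearest-neighbour parameters, ΔH in kcal/mol and ΔS in cal/(mol·K),
# 1 M NaCl reference.  10 unique Watson-Crick steps; the other 6 follow from
# the duplex symmetry XY ≡ reverse-complement(XY).
_NN_DH_DS = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

#: entropy salt correction per step, cal/(mol·K) per ln[Na+]
_SALT_DS = 0.368


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _default_step_energies(temperature: float = T_REF, na_molar: float = 0.1) -> dict[str, float]:
    """Step stabilities alpha (kBT, positive) for all 16 dinucleotide steps."""
    table: dict[str, float] = {}
    for a in "ACGT":
        for b in "ACGT":
            step = a + b
            key = step if step in _NN_DH_DS else reverse_complement(step)
            dh, ds = _NN_DH_DS[key]
            ds = ds + _SALT_DS * np.log(na_molar)
            dg_kcal = dh - temperature * ds / 1000.0
            # stability is -ΔG, rescaled from kcal/mol to kBT at `temperature`
            table[step] = -dg_kcal / (KBT_KCAL_MOL * temperature / T_REF)
    return table


@dataclass
class NNModel:
    """Nearest-neighbour duplex model (kBT at `temperature`, 100 mM NaCl default).

    ``step_energies`` maps each 5'->3' dinucleotide step to its stability
    (positive kBT); ``initiation`` is the duplex initiation penalty and
    ``loop_penalty`` the hairpin end-loop formation free energy, both kBT.
    """

    step_energies: dict[str, float] = field(default_factory=_default_step_energies)
    initiation: float = 1.6
    loop_penalty: float = 4.0
    temperature: float = T_REF

    def __post_init__(self) -> None:
        if self.loop_penalty < 0:
            raise ValueError("loop_penalty must be >= 0")
        missing = [a + b for a in "ACGT" for b in "ACGT" if a + b not in self.step_energies]
        if missing:
            raise ValueError(f"step_energies missing steps: {missing}")

    def step(self, dinucleotide: str) -> float:
        return self.step_energies[dinucleotide]


@dataclass
class SSDNAModel:
    """Freely jointed chain for released ssDNA.

    Defaults (Kuhn length 1.5 nm, contour 0.59 nm/nt) give ~1 nm of tether
    gained per unzipped base pair (two nucleotides) at ~15 pN.
    """

    kuhn_length: float = 1.5
    contour_per_nt: float = 0.59
    temperature: float = T_REF

    def __post_init__(self) -> None:
        if self.kuhn_length <= 0 or self.contour_per_nt <= 0:
            raise ValueError("kuhn_length and contour_per_nt must be > 0")

    @property
    def kbt(self) -> float:
        return KBT_PN_NM * self.temperature / T_REF


@dataclass
class HairpinSequence:
    """Hairpin stem (5'->3' on the strand unzipped first) plus end loop.

    Base-pair index 1 is the first pair opened at the fork.
    """

    stem: str
    loop: str = "TTTT"

    def __post_init__(self) -> None:
        self.stem = self.stem.upper()
        self.loop = self.loop.upper()
        for pos, base in enumerate(self.stem, start=1):
            if base not in "ACGT":
                raise ValueError(f"invalid base {base!r} at stem position {pos}")
        if len(self.stem) < 2:
            raise ValueError("stem must contain at least 2 bp")

    def __len__(self) -> int:
        return len(self.stem)

    @property
    def n_bp(self) -> int:
        return len(self.stem)

    def reverse_complement(self) -> "HairpinSequence":
        """The same duplex unzipped from the opposite end."""
        return HairpinSequence(reverse_complement(self.stem), self.loop)


@dataclass
class Landscape:
    """Unzipping free energy G_F(n), kBT, indexed by bps unzipped n = 0..N."""

    force: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("landscape values must be finite")

    @property
    def n_bp(self) -> int:
        return len(self.values) - 1

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([np.arange(len(self.values)), self.values]),
            fmt=("%d", "%.6f"),
            delimiter="\t",
            header="n\tG_kBT",
            comments="",
        )


def step_energy_profile(seq: HairpinSequence, nn: NNModel) -> np.ndarray:
    """Per-bp opening free energies alpha_i (kBT, positive), length N.

    alpha_i is the nearest-neighbour stability of the step between bp i and
    bp i+1.  The last bp stacks against the loop rather than a Watson-Crick
    step; it is assigned the sequence-mean step energy, a neutral choice
    that keeps uniform sequences uniform and the total duplex stability
    invariant under unzipping the duplex from the other end.
    """
    stem = seq.stem
    alpha = np.empty(len(stem))
    for i in range(len(stem) - 1):
        alpha[i] = nn.step(stem[i : i + 2])
    alpha[-1] = alpha[:-1].mean()
    return alpha


def duplex_free_energy(seq: HairpinSequence, nn: NNModel) -> float:
    """Total duplex stability at zero force: sum(alpha) + initiation (kBT)."""
    return float(np.sum(step_energy_profile(seq, nn)) + nn.initiation)


def ssdna_extension(force, model: SSDNAModel | None = None):
    """FJC extension per nucleotide at `force` (nm).

    x(F) = L_nt * (coth(u) - 1/u),  u = F*b/kBT.
    """
    model = model or SSDNAModel()
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    u = f * model.kuhn_length / model.kbt
    with np.errstate(invalid="ignore", over="ignore"):
        langevin = np.where(
            u < 1e-8,
            u / 3.0,  # small-force expansion, avoids 0/0
            1.0 / np.tanh(np.where(u < 1e-8, 1.0, u)) - 1.0 / np.where(u < 1e-8, 1.0, u),
        )
    out = model.contour_per_nt * langevin
    return float(out) if np.isscalar(force) else out


def ssdna_free_energy(force, model: SSDNAModel | None = None):
    """Stretching free-energy gain per released nucleotide (kBT, >= 0).

    Integral of the FJC extension from 0 to F, closed form
    (L_nt/b) * ln(sinh(u)/u).
    """
    model = model or SSDNAModel()
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    u = f * model.kuhn_length / model.kbt
    # log(sinh(u)/u) computed stably: u + log1p(-exp(-2u)) - log(2u)
    safe_u = np.where(u < 1e-8, 1.0, u)
    g_large = safe_u + np.log1p(-np.exp(-2.0 * safe_u)) - np.log(2.0 * safe_u)
    g = np.where(u < 1e-8, u * u / 6.0, g_large)
    out = (model.contour_per_nt / model.kuhn_length) * g
    return float(out) if np.isscalar(force) else out


def landscape(
    seq: HairpinSequence,
    force: float,
    nn: NNModel | None = None,
    ss: SSDNAModel | None = None,
) -> Landscape:
    """Unzipping free-energy landscape G_F(n) for n = 0..N, kBT.

    Folded-state reference G_F(0) = 0; opening bp i costs alpha_i and gains
    2*g_ss(F).  Consecutive values obey the exact telescoping relation
    G_F(n+1) - G_F(n) = alpha_{n+1} - 2*g_ss(F) for every n < N.  The
    constant loop term cancels in all differences and is omitted.
    """
    nn = nn or NNModel()
    ss = ss or SSDNAModel()
    alpha = step_energy_profile(seq, nn)
    n_arr = np.arange(len(alpha) + 1)
    g_ss = ssdna_free_energy(float(force), ss)
    values = np.concatenate([[0.0], np.cumsum(alpha)]) - n_arr * 2.0 * g_ss
    return Landscape(force=float(force), values=values)


def coexistence_force(
    seq: HairpinSequence,
    nn: NNModel | None = None,
    ss: SSDNAModel | None = None,
    bracket: tuple[float, float] = (1e-3, 50.0),
    tol: float = 1e-9,
) -> float:
    """Force at which folded and fully unzipped hairpin are isoenergetic (pN).

    Solved by bisection of G_F(0) - G_F(N) on `bracket`; typical designed
    hairpins fall between 13 and 16 pN.
    """
    nn = nn or NNModel()
    ss = ss or SSDNAModel()

    def gap(f: float) -> float:
        ls = landscape(seq, f, nn, ss)
        return float(ls.values[0] - ls.values[-1])

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"no coexistence force in bracket ({lo}, {hi}] pN: "
            f"gap({lo})={g_lo:.3g}, gap({hi})={g_hi:.3g}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gap(lo) * gap(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def max_barrier(ls: Landscape) -> float:
    """Largest forward barrier max_{i<j} (G(j) - G(i)), kBT (>= 0)."""
    values = ls.values
    running_min = np.minimum.accumulate(values)
    return float(max(np.max(values[1:] - running_min[:-1]), 0.0))


def roughness(seq: HairpinSequence, nn: NNModel | None = None) -> float:
    """Landscape roughness R: squared deviation of the cumulative step-energy
    profile from the linear ramp, R = sum_j (sum_{i<=j} alpha_i - j*alpha_mean)^2.

    R = 0 iff all alpha_i are equal; minimizing R flattens G_F(n).
    """
    nn = nn or NNModel()
    alpha = step_energy_profile(seq, nn)
    return roughness_of_profile(alpha)


def roughness_of_profile(alpha: np.ndarray) -> float:
    alpha = np.asarray(alpha, dtype=float)
    cum = np.cumsum(alpha)
    j = np.arange(1, len(alpha) + 1)
    dev = cum - j * alpha.mean()
    return float(np.sum(dev * dev))
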