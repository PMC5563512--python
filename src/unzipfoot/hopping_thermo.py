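"""Ligand binding energy from equilibrium hopping traces.

At a force F_hop inside the hopping window the molecule jumps between the
partially unzipped configurations blocked at the ligand sites.  The
extension histogram shows one Gaussian mode per configuration; the relative
Gaussian weights A_i give the populations p_i = A_i / sum(A).  Pairs of
populations then yield free-energy differences kBT*ln(p_j/p_i) which, after
subtracting the known duplex (nearest-neighbour) and ssDNA-stretching
contributions of the bps separating the two fork positions, leave the
per-site ligand binding free energy dG_int.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .energy_model import (
    HairpinSequence,
    NNModel,
    SSDNAModel,
    ssdna_extension,
    ssdna_free_energy,
    step_energy_profile,
)

__all__ = ["HoppingAnalysis", "hopping_populations", "binding_energy_from_populations"]


@dataclass
class HoppingAnalysis:
    """Populations and pairwise free energies of the blocked configurations."""

    F_hop: float
    levels_nm: np.ndarray  # fitted Gaussian centers, sorted ascending
    sigmas_nm: np.ndarray
    weights: np.ndarray  # Gaussian weights A_i / sum(A) = populations p_i
    positions_bp: np.ndarray | None = None

    @property
    def populations(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def hopping_populations(
    trace: pd.DataFrame,
    n_components: int,
    expected_levels=None,
    random_state: int = 0,
    max_samples: int = 300_000,
) -> HoppingAnalysis:
    """Gaussian-mixture fit of the extension histogram of a hopping trace.

    Fits `n_components` Gaussians to the emitted extension (initialized at
    `expected_levels` when provided); populations are the mixture weights.
    Raises if two components collapse onto the same level.
    """
    ext = trace["extension_nm"].to_numpy(dtype=float)
    meta = trace.attrs.get("meta", {})
    if len(ext) == 0:
        raise ValueError("empty hopping trace")
    if len(ext) > max_samples:
        step = len(ext) // max_samples + 1
        ext = ext[::step]
    x = ext.reshape(-1, 1)
    means_init = None
    if expected_levels is not None:
        means_init = np.asarray(expected_levels, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="spherical",
        means_init=means_init,
        random_state=random_state,
        n_init=1 if means_init is not None else 5,
    ).fit(x)
    centers = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_)
    weights = gm.weights_
    order = np.argsort(centers)
    centers, sigmas, weights = centers[order], sigmas[order], weights[order]
    gaps = np.diff(centers)
    if np.any(gaps < 1.5 * (sigmas[:-1] + sigmas[1:])):
        raise ValueError(
            "Gaussian components collapsed: fitted levels "
            f"{np.round(centers, 2).tolist()} with sigmas "
            f"{np.round(sigmas, 2).tolist()} are not separated"
        )
    return HoppingAnalysis(
        F_hop=float(meta.get("F_hop", trace["force_pN"].iloc[0])),
        levels_nm=centers,
        sigmas_nm=sigmas,
        weights=weights,
    )


def binding_energy_from_populations(
    populations,
    positions_bp,
    F_hop: float,
    seq: HairpinSequence,
    nn: NNModel | None = None,
    ss: SSDNAModel | None = None,
    bound_counts=None,
    all_pairs: bool = False,
) -> tuple[float, float, pd.DataFrame]:
    """Invert the hopping free-energy decomposition for dG_int (kBT).

    For configurations i (fork at n_i bp) and j (n_j > n_i), Boltzmann gives
    kBT ln(p_j/p_i) = -dDG0_{i,j} + dG_ss_{i,j} - (c_i - c_j)*dG_int, with
    dDG0 the nearest-neighbour free energy of bps n_i+1..n_j, dG_ss the
    stretching gain 2*(n_j - n_i)*g_ss(F_hop) and c_i the number of ligands
    bound in configuration i (default: one ligand released per forward hop).
    Returns (mean dG_int over adjacent pairs, spread, per-pair table); pairs
    with a zero population are excluded.
    """
    nn = nn or NNModel()
    ss = ss or SSDNAModel()
    p = np.asarray(populations, dtype=float)
    n = np.asarray(positions_bp, dtype=int)
    if len(p) != len(n) or len(p) < 2:
        raise ValueError("need matching populations and positions for >= 2 states")
    order = np.argsort(n)
    p, n = p[order], n[order]
    if bound_counts is None:
        c = np.arange(len(n), 0, -1)  # deeper fork -> fewer ligands still bound
    else:
        c = np.asarray(bound_counts, dtype=int)[order]
    alpha = step_energy_profile(seq, nn)
    cum = np.concatenate([[0.0], np.cumsum(alpha)])
    g_ss = ssdna_free_energy(float(F_hop), ss)

    pairs = (
        [(i, j) for i in range(len(n)) for j in range(i + 1, len(n))]
        if all_pairs
        else [(i, i + 1) for i in range(len(n) - 1)]
    )
    rows = []
    for i, j in pairs:
        if p[i] <= 0 or p[j] <= 0:
            continue
        ddg0 = cum[n[j]] - cum[n[i]]
        dg_ss = 2.0 * (n[j] - n[i]) * g_ss
        dc = c[i] - c[j]
        if dc == 0:
            continue
        dg_int = (-np.log(p[j] / p[i]) - ddg0 + dg_ss) / dc
        rows.append(
            {
                "i": int(n[i]),
                "j": int(n[j]),
                "ln_pj_over_pi": float(np.log(p[j] / p[i])),
                "ddg0_kBT": float(ddg0),
                "dg_ss_kBT": float(dg_ss),
                "n_ligands_released": int(dc),
                "dg_int_kBT": float(dg_int),
            }
        )
    if not rows:
        raise ValueError("no usable configuration pairs (zero populations?)")
    table = pd.DataFrame(rows)
    return float(table["dg_int_kBT"].mean()), float(table["dg_int_kBT"].std(ddof=0)), table
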