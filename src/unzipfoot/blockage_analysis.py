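"""From traces to blockage positions: alignment, detection, histograms, motifs.

The detection-phase extension of each cycle is aligned by subtracting that
cycle's mean phase-3 (fully open) extension, which collapses cycles on a
common reference and removes slow drift.  Aligned levels are negative for
blocked states and convert linearly to base-pair positions through the
ssDNA extension at the detection force: a blockage at aligned level z sits
at bp position N + z / (2*x_ss(F_test)).  Plateaus are detected as maximal
runs of samples within a level tolerance; per-bead position histograms are
fitted with Gaussian mixtures (component count by BIC) and per-bead peak
centers are pooled across beads.  Motif-level blockage probabilities assign
each event to its nearest bp and tally the sequence motif found there, both
raw and normalized by the motif's occurrence count in the stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import medfilt
from sklearn.mixture import GaussianMixture

from .energy_model import HairpinSequence, SSDNAModel, ssdna_extension

__all__ = [
    "BlockageEvent",
    "PeakSet",
    "align_cycles",
    "extension_to_bp",
    "detect_blockages",
    "fit_position_histogram",
    "aggregate_beads",
    "motif_blockage_probability",
]


@dataclass
class BlockageEvent:
    """One detected plateau during the detection phase."""

    bead: int
    cycle: int
    level: float  # aligned nm (negative for blocked states)
    position: float  # real-valued bp
    dwell: float  # s
    censored: bool = False
    censor_limit: float | None = None  # s from plateau start to phase end

    def __post_init__(self) -> None:
        if self.dwell <= 0:
            raise ValueError("dwell must be > 0")


@dataclass
class PeakSet:
    """Gaussian components fitted to a position histogram."""

    centers: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    residual: float = 0.0
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or self.weights.sum() > 1.000001:
            raise ValueError("weights must be >= 0 and sum to <= 1")
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be > 0")
        order = np.argsort(self.centers)
        self.centers = self.centers[order]
        self.sigmas = self.sigmas[order]
        self.weights = self.weights[order]

    @property
    def n_components(self) -> int:
        return len(self.centers)


def align_cycles(trace: pd.DataFrame) -> pd.DataFrame:
    """Phase-2 samples with extension re-referenced to the cycle's phase-3 mean.

    Returns the phase-2 rows with an extra ``aligned_nm`` column; cycles
    missing phase 2 or 3 are skipped (their count is in
    ``df.attrs['skipped_cycles']``).  Fully open phase-2 samples align to ~0.
    """
    out = []
    skipped = 0
    for (bead, cycle), grp in trace.groupby(["bead", "cycle"], sort=True):
        p2 = grp[grp["phase"] == 2]
        p3 = grp[grp["phase"] == 3]
        if p2.empty or p3.empty:
            skipped += 1
            continue
        ref = p3["extension_nm"].mean()
        p2 = p2.copy()
        p2["aligned_nm"] = p2["extension_nm"] - ref
        out.append(p2)
    if not out:
        result = trace.iloc[0:0].copy()
        result["aligned_nm"] = pd.Series(dtype=float)
    else:
        result = pd.concat(out, ignore_index=True)
    result.attrs["skipped_cycles"] = skipped
    result.attrs["meta"] = trace.attrs.get("meta", {})
    return result


def extension_to_bp(
    aligned_level,
    F_test: float,
    ss: SSDNAModel | None = None,
    N: int | None = None,
):
    """Convert an aligned level (nm, <= 0 when blocked) to a bp position.

    position = N + aligned_level / (2 * x_ss(F_test)); a fully open molecule
    (aligned 0) maps to N.
    """
    ss = ss or SSDNAModel()
    if N is None:
        raise ValueError("hairpin length N is required")
    factor = 2.0 * ssdna_extension(float(F_test), ss)
    if factor <= 0:
        raise ValueError(f"nonpositive nm-per-bp conversion factor at F={F_test} pN")
    return N + np.asarray(aligned_level, dtype=float) / factor


def detect_blockages(
    aligned: pd.DataFrame,
    min_dwell: float = 0.1,
    level_tolerance: float = 4.0,
    F_test: float | None = None,
    ss: SSDNAModel | None = None,
    N: int | None = None,
) -> list[BlockageEvent]:
    """Detect blockage plateaus in aligned phase-2 samples.

    A plateau is a maximal run of samples whose values stay within
    ±level_tolerance/2 of the running plateau mean, lasting at least
    `min_dwell`; runs at the open level (aligned ~ 0 within the tolerance)
    are the fully unzipped state and are not events.  A plateau that
    persists to the end of its cycle's detection phase is flagged censored.
    """
    ss = ss or SSDNAModel()
    meta = aligned.attrs.get("meta", {})
    if F_test is None:
        F_test = meta.get("F_test")
    if N is None:
        stem = meta.get("stem")
        N = len(stem) if stem else None
    if F_test is None or N is None:
        raise ValueError("F_test and N must be given or present in trace metadata")

    events: list[BlockageEvent] = []
    for (bead, cycle), grp in aligned.groupby(["bead", "cycle"], sort=True):
        values = grp["aligned_nm"].to_numpy()
        times = grp["time_s"].to_numpy()
        if len(values) == 0:
            continue
        dt = np.median(np.diff(times)) if len(times) > 1 else 0.0
        # median filter suppresses single-sample noise excursions that would
        # otherwise chop one plateau into several runs
        smooth = medfilt(values, 5) if len(values) >= 5 else values
        runs = _segment_runs(smooth, level_tolerance / 2.0)
        runs = _merge_runs(smooth, runs, level_tolerance / 2.0)
        for start, stop in runs:
            # median is robust to boundary samples bleeding in from the
            # neighbouring level on short plateaus
            level = float(np.median(values[start:stop]))
            dwell = (stop - start) * dt
            if dwell < min_dwell or dwell <= 0:
                continue
            if level > -level_tolerance:  # open state, not a blockage
                continue
            events.append(
                BlockageEvent(
                    bead=int(bead),
                    cycle=int(cycle),
                    level=level,
                    position=float(extension_to_bp(level, F_test, ss, N)),
                    dwell=dwell,
                    censored=stop == len(values),
                    censor_limit=(len(values) - start) * dt,
                )
            )
    return events


def _segment_runs(values: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Maximal runs whose samples stay within ±tol of the running mean."""
    runs = []
    start = 0
    mean = values[0]
    count = 1
    for i in range(1, len(values)):
        if abs(values[i] - mean) <= tol:
            count += 1
            mean += (values[i] - mean) / count
        else:
            runs.append((start, i))
            start, mean, count = i, values[i], 1
    runs.append((start, len(values)))
    return runs


def _merge_runs(
    values: np.ndarray, runs: list[tuple[int, int]], tol: float
) -> list[tuple[int, int]]:
    """Re-join adjacent runs split by noise excursions (means within tol)."""
    merged = [runs[0]]
    for start, stop in runs[1:]:
        pstart, pstop = merged[-1]
        if abs(np.mean(values[start:stop]) - np.mean(values[pstart:pstop])) <= tol:
            merged[-1] = (pstart, stop)
        else:
            merged.append((start, stop))
    return merged


def fit_position_histogram(
    events: list[BlockageEvent] | np.ndarray,
    bin_bp: float = 1.0,
    max_components: int = 5,
    random_state: int = 0,
    reg_covar: float = 1e-4,
) -> PeakSet:
    """Gaussian-mixture fit of event positions; component count by BIC.

    Fits mixtures of 1..max_components Gaussians to the (real-valued bp)
    positions and keeps the BIC-optimal one.  A component narrower than a
    quarter bin flags the fit degenerate.
    """
    if isinstance(events, np.ndarray):
        positions = events.astype(float)
    else:
        positions = np.asarray(
            [e.position if isinstance(e, BlockageEvent) else e for e in events],
            dtype=float,
        )
    if len(positions) == 0:
        raise ValueError("no events to fit")
    x = positions.reshape(-1, 1)
    fits = []
    for k in range(1, min(max_components, len(positions)) + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="spherical",
            random_state=random_state,
            n_init=3,
            reg_covar=reg_covar,
        ).fit(x)
        fits.append((gm.bic(x), k, gm))
    # parsimony rule: smallest component count within 10 BIC of the optimum
    best_bic = min(f[0] for f in fits)
    gm = next(f[2] for f in fits if f[0] <= best_bic + 10.0)
    sigmas = np.sqrt(gm.covariances_)
    peaks = PeakSet(
        centers=gm.means_.ravel(),
        sigmas=sigmas,
        weights=gm.weights_,
        residual=float(-gm.score(x)),
    )
    peaks.degenerate = bool(np.any(peaks.sigmas < bin_bp / 4.0))
    return peaks


def aggregate_beads(
    peaksets: list[PeakSet],
    bin_bp: float = 1.0,
    max_components: int = 5,
    random_state: int = 0,
) -> tuple[pd.DataFrame, PeakSet]:
    """Pool per-bead peak centers into a blockage-position distribution.

    Returns a histogram table (bin center, count, and error bars inversely
    proportional to the square root of the number of points in the bin;
    empty bins have undefined error) and a Gaussian fit of the pooled
    centers.
    """
    if not peaksets:
        raise ValueError("no per-bead peak sets")
    centers = np.concatenate([p.centers for p in peaksets])
    lo = np.floor(centers.min() - 2)
    hi = np.ceil(centers.max() + 2)
    edges = np.arange(lo, hi + bin_bp, bin_bp)
    counts, edges = np.histogram(centers, bins=edges)
    hist = pd.DataFrame(
        {
            "position_bp": 0.5 * (edges[:-1] + edges[1:]),
            "count": counts,
            "error": np.where(counts > 0, 1.0 / np.sqrt(np.maximum(counts, 1)), np.nan),
        }
    )
    if len(centers) <= max_components:
        fitted = PeakSet(
            centers=centers,
            sigmas=np.full(len(centers), bin_bp / 2.0),
            weights=np.full(len(centers), 1.0 / len(centers)),
        )
    else:
        # pooled centers cannot be resolved below the histogram bin: keep a
        # bin-scale variance floor so a stray bead widens a peak instead of
        # spawning one
        fitted = fit_position_histogram(
            centers, bin_bp=bin_bp, max_components=max_components,
            random_state=random_state, reg_covar=bin_bp**2,
        )
    return hist, fitted


def motif_blockage_probability(
    events: list[BlockageEvent],
    seq: HairpinSequence,
    motif_len: int = 2,
) -> pd.DataFrame:
    """Blockage probability per sequence motif, raw and frequency-normalized.

    Each event is assigned to its nearest bp position p (round half-up); the
    tallied motif is the tetramer starting at bp p (motif_len 4) or the
    dinucleotide step one bp into the stabilized span (motif_len 2), i.e.
    the CpG of an XCGY site blocked at p.  Raw probabilities sum to 1 over
    motifs; the normalized column divides by the motif's occurrence count in
    the stem and renormalizes.  Motifs absent from the stem have undefined
    (NaN) probabilities rather than zero.
    """
    if motif_len not in (2, 4):
        raise ValueError("motif_len must be 2 or 4")
    stem = seq.stem
    offset = 1 if motif_len == 2 else 0
    import itertools

    motifs = ["".join(p) for p in itertools.product("ACGT", repeat=motif_len)]
    occurrences = {
        m: sum(1 for i in range(len(stem) - motif_len + 1) if stem[i : i + motif_len] == m)
        for m in motifs
    }
    tally = dict.fromkeys(motifs, 0)
    total = 0
    for e in events:
        p = int(np.floor(e.position + 0.5))  # nearest bp, half-up
        start = p - 1 + offset  # 0-based index of the motif's first base
        if start < 0 or start + motif_len > len(stem):
            continue
        tally[stem[start : start + motif_len]] += 1
        total += 1
    raw = {m: (tally[m] / total if total else np.nan) for m in motifs}
    norm_unscaled = {
        m: (raw[m] / occurrences[m] if occurrences[m] > 0 else np.nan) for m in motifs
    }
    norm_total = np.nansum(list(norm_unscaled.values()))
    normalized = {
        m: (v / norm_total if np.isfinite(v) and norm_total > 0 else v)
        for m, v in norm_unscaled.items()
    }
    return pd.DataFrame(
        {
            "motif": motifs,
            "count": [tally[m] for m in motifs],
            "occurrences": [occurrences[m] for m in motifs],
            "raw": [raw[m] for m in motifs],
            "normalized": [normalized[m] for m in motifs],
        }
    ).set_index("motif")
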