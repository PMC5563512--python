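"""Mechanical footprints and recognition-sequence recovery.

A large DNA-binding protein stalls the unzipping fork at its boundary
contacts ("head" and "back"), which are shifted with respect to the
recognition site.  The mechanical footprint (MFP) — the DNA span the
protein covers — is the sum of the shifts measured in the two binding
orientations plus the recognition-site length; for a symmetric
(palindrome-binding) protein the two shifts are equal and MFP =
2*shift + site length.

When the recognition site occurs more than once, its sequence can be
recovered by a similarity analysis around the blockage positions: windows
of K bases are compared position-wise for identity (C) and in reversed
order for complementarity (C'), and the similarity S = max(C, C') reaches
K exactly when the two windows carry the same duplex motif in either
orientation.  Forward + reverse-complement constructs (the test sequence,
a spacer, then its reverse complement) present every site in both
orientations; a position in the forward region has a mirror-image position
in the reverse region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FootprintResult",
    "mfp",
    "similarity",
    "recognition_search",
    "mirror_positions",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class FootprintResult:
    shifts: tuple
    site_length: int
    mfp: int
    symmetric: bool


def mfp(shifts, site_length: int, symmetric: bool) -> int:
    """Mechanical footprint in bp.

    Symmetric binding: MFP = 2*shift + site_length (one shift expected).
    Asymmetric binding: MFP = shift1 + shift2 + site_length (two shifts).
    """
    shifts = tuple(int(s) for s in shifts)
    if any(s < 0 for s in shifts):
        raise ValueError("shifts must be >= 0")
    if symmetric:
        if len(shifts) != 1:
            raise ValueError("symmetric binding takes exactly one shift")
        return 2 * shifts[0] + site_length
    if len(shifts) != 2:
        raise ValueError("asymmetric binding takes exactly two shifts")
    return shifts[0] + shifts[1] + site_length


def similarity(seq: str, i: int, j: int, K: int = 4) -> int:
    """Similarity S(i, j) between the K-windows at 1-based positions i and j.

    C counts position-wise base identity over the K bases; C' counts
    complementarity between base i+k and base j+K-1-k (the window read in
    the other duplex orientation); S = max(C, C') in 0..K, with S = K when
    the windows coincide or are reverse complements.
    """
    seq = seq.upper()
    if i < 1 or j < 1 or i + K - 1 > len(seq) or j + K - 1 > len(seq):
        raise ValueError(f"windows [{i},{i+K-1}] / [{j},{j+K-1}] outside sequence 1..{len(seq)}")
    a = seq[i - 1 : i - 1 + K]
    b = seq[j - 1 : j - 1 + K]
    c = sum(1 for k in range(K) if a[k] == b[k])
    c_prime = sum(1 for k in range(K) if _COMPLEMENT.get(a[k]) == b[K - 1 - k])
    return max(c, c_prime)


def recognition_search(
    seq: str,
    blockage_positions,
    K: int = 4,
    half_window: int = 10,
    exclude=None,
):
    """Candidate recognition sequences near repeated blockage positions.

    Scans windows of `half_window` bp on both sides of every (rounded)
    blockage position, scores all cross-blockage window pairs with the
    similarity S, and returns the K-mers achieving S = K, ranked by summed
    distance to their blockage positions.  Requires >= 2 blockages (at
    least two repeats of the recognition sequence are needed); returns an
    empty list when no repeat exists.  `exclude` is an optional (start, end)
    1-based inclusive range (e.g. a spacer) whose windows are skipped.

    Returns a list of dicts with keys sequence, i, j, score, rank_distance.
    """
    seq = seq.upper()
    positions = sorted({int(np.floor(p + 0.5)) for p in blockage_positions})
    if len(positions) < 2:
        raise ValueError("insufficient repeats: need >= 2 blockage positions")

    def windows(p):
        lo = max(1, p - half_window)
        hi = min(len(seq) - K + 1, p + half_window)
        for s in range(lo, hi + 1):
            if exclude and not (s + K - 1 < exclude[0] or s > exclude[1]):
                continue
            yield s

    hits = {}
    for a_idx in range(len(positions)):
        for b_idx in range(a_idx + 1, len(positions)):
            pa, pb = positions[a_idx], positions[b_idx]
            for i in windows(pa):
                for j in windows(pb):
                    if similarity(seq, i, j, K) == K:
                        kmer = seq[i - 1 : i - 1 + K]
                        rc = "".join(_COMPLEMENT[b] for b in reversed(kmer))
                        canon = min(kmer, rc)
                        dist = abs(i - pa) + abs(j - pb)
                        prev = hits.get(canon)
                        if prev is None or dist < prev["rank_distance"]:
                            hits[canon] = {
                                "sequence": canon,
                                "i": i,
                                "j": j,
                                "score": K,
                                "rank_distance": dist,
                            }
    return sorted(hits.values(), key=lambda h: (h["rank_distance"], h["sequence"]))


def mirror_positions(seq_forward_len: int, spacer_len: int, position: int) -> int:
    """Mirror a 1-based bp position between the forward and reverse-complement
    regions of a forward–spacer–reverse construct.

    Position p in the forward region [1, L] maps to 2L + spacer + 1 - p in
    the reverse region (and vice versa); the map is an involution.  Spacer
    positions have no mirror image.
    """
    L, s = int(seq_forward_len), int(spacer_len)
    total = 2 * L + s
    if not 1 <= position <= total:
        raise ValueError(f"position {position} outside construct 1..{total}")
    if L < position <= L + s:
        raise ValueError(f"position {position} lies in the spacer {L+1}..{L+s}")
    return total + 1 - position
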