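"""Synthetic single-molecule traces: force-cycle unzipping and equilibrium hopping.

The force-cycle (FC) protocol alternates three forces in five phases:
(1) F_low — hairpin folded, ligands bind; (2) F_test — hairpin unzips
cooperatively and stalls at every bound ligand, producing extension plateaus;
(3) F_high — remaining ligands are stripped and the hairpin opens fully;
(4) back to F_test — reference extension of the open hairpin (Z_open);
(5) F_low — the hairpin refolds.  A ligand blocking the fork at base pair p
holds the extension at 2*p*x_ss(F_test); its dwell is exponential with the
Bell-Evans rate k = k0*exp(F*Xdag/kBT).

Extensions are recorded force-normalized to the detection force: the
deterministic elastic offset between phases at different forces carries no
information and is removed at acquisition, so the phase-3 reference aligns
the open state to zero downstream.  Slow drift (an Ornstein-Uhlenbeck
wander plus a static per-bead offset) and white Gaussian noise are added on
top.

Equilibrium hopping traces hold a fixed force F_hop and jump between the
partially unzipped configurations blocked at each ligand site, as a
continuous-time Markov chain whose stationary law is Boltzmann in the
configuration free energies (landscape value minus the binding energy of
the ligands still bound).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import KBT_PN_NM
from .energy_model import (
    HairpinSequence,
    NNModel,
    SSDNAModel,
    coexistence_force,
    landscape,
    ssdna_extension,
)

__all__ = [
    "ProtocolSpec",
    "LigandSite",
    "LigandModel",
    "simulate_fc_traces",
    "simulate_hopping",
    "write_traces",
    "read_traces",
]

TRACE_COLUMNS = ["bead", "cycle", "phase", "time_s", "force_pN", "extension_nm"]


@dataclass
class ProtocolSpec:
    """Five-phase force cycle protocol (forces pN, durations s, rate Hz)."""

    F_low: float = 6.0
    F_test: float = 17.0
    F_high: float = 25.0
    F_hop: float = 15.5
    phase_durations: tuple[float, float, float, float, float] = (1.0, 4.0, 1.0, 1.0, 1.0)
    sampling_rate: float = 30.0
    n_cycles: int = 100
    n_beads: int = 1

    def __post_init__(self) -> None:
        if not (self.F_low < self.F_test < self.F_high):
            raise ValueError("forces must satisfy F_low < F_test < F_high")
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be > 0")


@dataclass
class LigandSite:
    """One ligand binding site on the stem.

    `position` is the first stabilized bp (the fork stalls there having
    unzipped `position` bps); `span` the number of stabilized bps (4 for a
    bis-intercalator clamping XCGY); `k0`/`xdag` the Bell-Evans zero-force
    unbinding rate and transition-state distance; `dg_int` the binding free
    energy; `occupancy` optionally overrides the concentration/Kd value.
    `cooperative_with_next` merges this site and the next into one composite
    block (joint occupancy, doubled xdag).
    """

    position: int
    span: int = 4
    k0: float = 1e-4
    xdag: float = 2.0
    dg_int: float = 7.0
    occupancy: float | None = None
    cooperative_with_next: bool = False

    def __post_init__(self) -> None:
        if self.k0 <= 0 or self.xdag <= 0:
            raise ValueError("k0 and xdag must be > 0")
        if self.occupancy is not None and not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class LigandModel:
    """Ligand sites plus binding equilibrium (concentration/Kd or occupancy)."""

    sites: list[LigandSite] = field(default_factory=list)
    concentration: float | None = None
    kd: float | None = None

    def site_occupancy(self, site: LigandSite) -> float:
        if site.occupancy is not None:
            return site.occupancy
        if self.concentration is not None and self.kd is not None:
            return self.concentration / (self.concentration + self.kd)
        return 1.0

    def validate_against(self, seq: HairpinSequence) -> None:
        for s in self.sites:
            if not 1 <= s.position <= seq.n_bp:
                raise ValueError(f"site position {s.position} outside stem 1..{seq.n_bp}")


def _bell_evans_rate(k0: float, xdag: float, force: float) -> float:
    return k0 * np.exp(force * xdag / KBT_PN_NM)


def _effective_blocks(ligand: LigandModel, rng: np.random.Generator):
    """Sample occupied sites for one cycle and merge cooperative pairs into
    composite blocks of doubled xdag at the earlier position."""
    blocks = []
    i = 0
    sites = sorted(ligand.sites, key=lambda s: s.position)
    while i < len(sites):
        s = sites[i]
        if s.cooperative_with_next and i + 1 < len(sites):
            if rng.random() < ligand.site_occupancy(s):
                blocks.append(replace(s, xdag=2 * s.xdag, cooperative_with_next=False))
            i += 2
        else:
            if rng.random() < ligand.site_occupancy(s):
                blocks.append(s)
            i += 1
    return blocks


def _ou_drift(n: int, dt: float, rate: float, rng: np.random.Generator,
              tau: float = 30.0) -> np.ndarray:
    """Slow Ornstein-Uhlenbeck wander with stationary s.d. `rate*tau` nm scale.

    `rate` is the nm/s magnitude of the wander; rate 0 gives exactly zero."""
    if rate == 0 or n == 0:
        return np.zeros(n)
    x = np.empty(n)
    sigma = rate * np.sqrt(tau / 2.0)
    x[0] = sigma * rng.standard_normal()
    a = np.exp(-dt / tau)
    b = sigma * np.sqrt(1 - a * a)
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * rng.standard_normal()
    return x


def simulate_fc_traces(
    seq: HairpinSequence,
    ligand: LigandModel,
    protocol: ProtocolSpec,
    nn: NNModel | None = None,
    ss: SSDNAModel | None = None,
    noise_sd: float = 1.0,
    drift_rate: float = 0.05,
    seed: int = 0,
    ligand_survival: float = 0.0,
) -> pd.DataFrame:
    """Simulate FC-protocol traces for every bead and cycle.

    Unzipping at F_test >> F_c is cooperative: the fork advances instantly
    between occupied sites, so phase 2 is a staircase of plateaus at
    2*p*x_ss(F_test) with exponential Bell-Evans dwells.  Phase 3 strips all
    ligands (unless `ligand_survival` > 0) and always reaches full extension;
    phase 4 records Z_open at F_test.  Fixed seed gives identical output.
    """
    nn = nn or NNModel()
    ss = ss or SSDNAModel()
    ligand.validate_against(seq)
    fc = coexistence_force(seq, nn, ss)
    if protocol.F_test <= fc:
        raise ValueError(
            f"F_test={protocol.F_test} pN must exceed the coexistence force "
            f"({fc:.2f} pN) for cooperative unzipping"
        )
    rng = np.random.default_rng(seed)
    dt = 1.0 / protocol.sampling_rate
    x_nt = ssdna_extension(protocol.F_test, ss)
    open_level = 2.0 * seq.n_bp * x_nt
    phase_n = [max(1, int(round(d * protocol.sampling_rate))) for d in protocol.phase_durations]
    cycle_n = sum(phase_n)
    forces = [protocol.F_low, protocol.F_test, protocol.F_high, protocol.F_test, protocol.F_low]

    frames = []
    for bead in range(protocol.n_beads):
        # static per-bead offset scales with the drift magnitude (zero drift
        # means a perfectly referenced bead: plateau levels are then exact)
        offset = 40.0 * drift_rate * rng.standard_normal()
        n_total = cycle_n * protocol.n_cycles
        drift = _ou_drift(n_total, dt, drift_rate, rng) + offset
        t0 = 0.0
        idx = 0
        carried: list[LigandSite] = []
        for cycle in range(protocol.n_cycles):
            ext = np.empty(cycle_n)
            pos = 0
            # phase 1: folded at F_low; ligands bind
            ext[: phase_n[0]] = 0.0
            pos += phase_n[0]
            # phase 2: staircase of ligand blockages at F_test
            blocks = sorted(
                carried + _effective_blocks(ligand, rng), key=lambda s: s.position
            )
            carried = []
            seg = np.full(phase_n[1], open_level)
            t_used = 0.0
            for blk in blocks:
                rate = _bell_evans_rate(blk.k0, blk.xdag, protocol.F_test)
                dwell = rng.exponential(1.0 / rate)
                i0 = int(np.floor(t_used * protocol.sampling_rate))
                i1 = int(np.floor(min(t_used + dwell, protocol.phase_durations[1])
                                  * protocol.sampling_rate))
                seg[i0:i1] = 2.0 * blk.position * x_nt
                t_used += dwell
                if t_used >= protocol.phase_durations[1]:
                    break
            ext[pos : pos + phase_n[1]] = seg
            pos += phase_n[1]
            # phase 3: F_high strips ligands, fully open
            ext[pos : pos + phase_n[2]] = open_level
            pos += phase_n[2]
            if ligand_survival > 0:
                carried = [b for b in blocks if rng.random() < ligand_survival]
            # phase 4: Z_open reference at F_test
            ext[pos : pos + phase_n[3]] = open_level
            pos += phase_n[3]
            # phase 5: refold at F_low
            ext[pos : pos + phase_n[4]] = 0.0
            pos += phase_n[4]

            phase_col = np.repeat([1, 2, 3, 4, 5], phase_n)
            force_col = np.repeat(forces, phase_n)
            noise = noise_sd * rng.standard_normal(cycle_n)
            frames.append(
                pd.DataFrame(
                    {
                        "bead": bead,
                        "cycle": cycle,
                        "phase": phase_col,
                        "time_s": t0 + dt * np.arange(cycle_n),
                        "force_pN": force_col,
                        "extension_nm": ext + noise + drift[idx : idx + cycle_n],
                    }
                )
            )
            t0 += cycle_n * dt
            idx += cycle_n
    out = pd.concat(frames, ignore_index=True)
    out.attrs["meta"] = {
        "kind": "fc",
        "seed": seed,
        "noise_sd": noise_sd,
        "drift_rate": drift_rate,
        "stem": seq.stem,
        "loop": seq.loop,
        "F_low": protocol.F_low,
        "F_test": protocol.F_test,
        "F_high": protocol.F_high,
        "sampling_rate": protocol.sampling_rate,
        "n_cycles": protocol.n_cycles,
        "n_beads": protocol.n_beads,
    }
    return out


def hopping_configurations(
    seq: HairpinSequence,
    ligand: LigandModel,
    F_hop: float,
    nn: NNModel | None = None,
    ss: SSDNAModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Blocked-configuration fork positions and free energies at F_hop (kBT).

    Configuration i is the hairpin unzipped to site i's position; every site
    at or beyond the fork is still duplex-embedded and bound, each
    contributing -dg_int.
    """
    nn = nn or NNModel()
    ss = ss or SSDNAModel()
    sites = sorted(ligand.sites, key=lambda s: s.position)
    if not sites:
        raise ValueError("ligand model defines no sites")
    ls = landscape(seq, F_hop, nn, ss)
    positions = np.array([s.position for s in sites])
    energies = np.array(
        [
            ls.values[s.position]
            - sum(t.dg_int for t in sites if t.position >= s.position)
            for s in sites
        ]
    )
    return positions, energies


def choose_hopping_sites(
    seq: HairpinSequence,
    F_hop: float,
    dg_int: float = 7.0,
    n_sites: int = 3,
    motif: str = "CG",
    nn: NNModel | None = None,
    ss: SSDNAModel | None = None,
    margin: int = 10,
) -> list[int]:
    """Pick ligand-site positions whose blocked configurations are all
    measurably populated at F_hop.

    Experimentally, hopping is only observed in the narrow force window
    where the blocked configurations have comparable free energies; this
    helper mimics that selection.  Candidate positions are the bps one
    before each `motif` occurrence (the X of an XCGY site, so the CpG step
    is stabilized); the combination minimizing the spread of configuration
    free energies (landscape value minus dg_int per still-bound ligand) is
    returned.
    """
    nn = nn or NNModel()
    ss = ss or SSDNAModel()
    stem = seq.stem
    candidates = [
        i  # bp position of X in XCGY, 1-based: stem[i-1]=X, motif at i..i+1
        for i in range(margin, seq.n_bp - margin)
        if stem[i : i + len(motif)] == motif
    ]
    if len(candidates) < n_sites:
        raise ValueError(f"fewer than {n_sites} {motif} sites in the stem")
    ls = landscape(seq, F_hop, nn, ss)
    best: tuple[float, tuple[int, ...]] | None = None
    import itertools as _it

    for combo in _it.combinations(candidates, n_sites):
        g = [
            ls.values[p] - dg_int * (n_sites - k)
            for k, p in enumerate(combo)
        ]
        spread = max(g) - min(g)
        if best is None or spread < best[0]:
            best = (spread, combo)
    return list(best[1])


def simulate_hopping(
    seq: HairpinSequence,
    ligand: LigandModel,
    F_hop: float,
    duration: float,
    nn: NNModel | None = None,
    ss: SSDNAModel | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    sampling_rate: float = 30.0,
    attempt_rate: float = 5.0,
) -> pd.DataFrame:
    """Equilibrium hopping among ligand-blocked configurations at fixed F_hop.

    Nearest-neighbour continuous-time Markov jumps with rates
    k(i->j) = attempt_rate * exp(-(G_j - G_i)/2), which satisfy detailed
    balance, so long-run occupancies are Boltzmann in the configuration free
    energies.  Emitted extension is the configuration level plus Gaussian
    noise.
    """
    nn = nn or NNModel()
    ss = ss or SSDNAModel()
    ligand.validate_against(seq)
    if len(ligand.sites) < 2:
        raise ValueError("hopping requires at least 2 blocked configurations")
    rng = np.random.default_rng(seed)
    positions, energies = hopping_configurations(seq, ligand, F_hop, nn, ss)
    n_state = len(positions)
    x_nt = ssdna_extension(F_hop, ss)
    levels = 2.0 * positions * x_nt

    n_samples = int(round(duration * sampling_rate))
    dt = 1.0 / sampling_rate
    state = int(np.argmin(energies))
    state_path = np.empty(n_samples, dtype=np.int32)
    t = 0.0
    i_fill = 0
    while i_fill < n_samples:
        rates = {}
        for nb in (state - 1, state + 1):
            if 0 <= nb < n_state:
                rates[nb] = attempt_rate * np.exp(-(energies[nb] - energies[state]) / 2.0)
        total = sum(rates.values())
        wait = rng.exponential(1.0 / total)
        j_end = min(n_samples, int(np.floor((t + wait) * sampling_rate)) + 1)
        if j_end > i_fill:
            state_path[i_fill:j_end] = state
            i_fill = j_end
        t += wait
        u = rng.random() * total
        acc = 0.0
        for nb, r in rates.items():
            acc += r
            if u <= acc:
                state = nb
                break
    ext = levels[state_path] + noise_sd * rng.standard_normal(n_samples)
    out = pd.DataFrame(
        {
            "bead": 0,
            "cycle": 0,
            "phase": 0,
            "time_s": dt * np.arange(n_samples),
            "force_pN": F_hop,
            "extension_nm": ext,
        }
    )
    out.attrs["meta"] = {
        "kind": "hopping",
        "seed": seed,
        "noise_sd": noise_sd,
        "stem": seq.stem,
        "loop": seq.loop,
        "F_hop": F_hop,
        "duration": duration,
        "sampling_rate": sampling_rate,
        "site_positions": positions.tolist(),
        "levels_nm": levels.tolist(),
    }
    return out


def write_traces(traces: pd.DataFrame, path) -> None:
    """Write traces as TSV with a `# key=value` header block."""
    meta = traces.attrs.get("meta", {})
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        # default float formatting is the shortest round-trip repr: lossless
        traces.to_csv(fh, sep="\t", index=False)


def read_traces(path) -> pd.DataFrame:
    """Read traces written by :func:`write_traces`; header goes to attrs."""
    meta: dict[str, object] = {}
    body: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" not in stripped:
                    raise ValueError(f"malformed header at line {lineno}: {line!r}")
                key, val = stripped.split("=", 1)
                meta[key.strip()] = _parse_meta(val.strip())
            else:
                body.append(line)
    if not body:
        raise ValueError("trace file has no column header")
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t", float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file missing columns: {missing}")
    df.attrs["meta"] = meta
    return df


def _parse_meta(value: str):
    if value.startswith("[") and value.endswith("]"):
        inner = value[1:-1].strip()
        if not inner:
            return []
        return [_parse_meta(v.strip()) for v in inner.split(",")]
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value
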