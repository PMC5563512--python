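"""Locate ligand binding sites from simulated force-cycle traces.

A CpG-selective bis-intercalator occupies three sites on the hairpin.  Each
force cycle unzips the hairpin at F_test; the fork stalls at every bound
ligand, producing extension plateaus.  Aligning each cycle to its own
fully-open reference and converting nm to bp recovers the binding
positions with ~bp accuracy.
"""

import numpy as np

from unzipfoot import (
    DesignSpec,
    LigandModel,
    LigandSite,
    ProtocolSpec,
    align_cycles,
    detect_blockages,
    fit_position_histogram,
    initial_valid_sequence,
    motif_blockage_probability,
    simulate_fc_traces,
)

seq = initial_valid_sequence(DesignSpec(seed=7, steps=0))
# place the ligand on three well-separated XCGY sites (CpG step stabilized)
cg = [p for p in range(20, 150) if seq.stem[p : p + 2] == "CG"]
sites = [cg[0], cg[len(cg) // 2], cg[-1]]
ligand = LigandModel(
    sites=[LigandSite(position=p, k0=1e-4, xdag=2.0) for p in sites],
    concentration=300.0,  # nM, with Kd 100 nM -> 75% occupancy per cycle
    kd=100.0,
)
protocol = ProtocolSpec(F_low=6.0, F_test=17.0, F_high=25.0,
                        n_cycles=100, n_beads=5)
traces = simulate_fc_traces(seq, ligand, protocol, noise_sd=1.0,
                            drift_rate=0.05, seed=0)

events = detect_blockages(align_cycles(traces))
peaks = fit_position_histogram(events, max_components=4)
print(f"{len(events)} blockage events from "
      f"{protocol.n_beads} beads x {protocol.n_cycles} cycles")
print("fitted peaks (center / sigma / weight), truth at", sites)
for c, s, w in zip(peaks.centers, peaks.sigmas, peaks.weights):
    print(f"  {c:7.2f} bp   {s:4.2f} bp   {w:5.3f}")

table = motif_blockage_probability(events, seq, motif_len=2)
top = table.sort_values("raw", ascending=False).head(3)
print("top dinucleotide steps by raw blockage probability:")
print(np.round(top[["raw", "normalized", "occurrences"]], 3))
# Peak centers sit within ~1 bp of the injected sites; the dinucleotide
# table concentrates on the step the ligand stabilizes.
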