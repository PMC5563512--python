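# unzipfoot

Single-molecule DNA footprinting by mechanical unzipping, in silico: design
of flat-landscape hairpins that present every binding motif, synthesis of
magnetic-tweezers-style force-cycle and equilibrium-hopping traces with
ligand roadblocks, and the analysis chain that turns traces into binding
positions, unbinding kinetics, binding energies and mechanical footprints.

The package is for biophysicists and method developers working with
hairpin-unzipping footprinting assays who need the computational side of
the experiment: hairpin design, a faithful synthetic-data generator for
testing analysis code, and the estimators themselves.

## The model

A DNA hairpin with stem of `N` bp held under force `F` unzips sequentially.
With `n` bp open, its free energy relative to the folded state is

    G_F(n) = Σ_{i≤n} α_i − 2 n g_ss(F)        [kBT]

where `α_i` is the nearest-neighbour stability of bp `i` (unified NN
ΔH/ΔS at 25 °C, 100 mM NaCl) and `g_ss(F)` the stretching free energy per
released nucleotide under a freely jointed chain (Kuhn length 1.5 nm,
contour 0.59 nm/nt — about 1 nm of tether gained per unzipped bp at 15 pN).
The coexistence force `F_c` solves `G_F(0) = G_F(N)`; above it the hairpin
opens cooperatively unless a bound ligand stalls the fork, producing an
extension plateau at `2 p x_ss(F)` for a ligand at bp `p`.

Plateau dwell times follow the Bell-Evans law `k = k0 exp(F X† / kBT)`, so
`ln k` versus `F` yields the zero-force unbinding rate `k0` and the
transition-state distance `X†`.  In the hopping regime the Boltzmann
populations `p_i` of the blocked configurations obey

    kBT ln(p_j / p_i) = −ΔΔG⁰_{ij} + ΔG^ss_{ij}(F) − ΔG_int

from which the per-site ligand binding energy `ΔG_int` is solved using the
known duplex and ssDNA terms.  Hairpin design minimizes the landscape
roughness `R = Σ_j (Σ_{i≤j} α_i − j ᾱ)²` over sequences containing every
tetramer class (reverse-complement equivalence: 136 classes in a 170-bp
stem) at least once and not more than twice.  Footprints combine blockage
shifts from the two binding orientations: `MFP = shift₁ + shift₂ + site`
(`= 2·shift + site` for palindrome binders), and repeated recognition
sites are recovered by the similarity score `S = max(C, C′) ∈ 0..4` over
sequence windows.

## Worked example

`examples/unbinding_kinetics.py` injects a ligand with `k0 = 1e−4 s⁻¹`,
`X† = 2 nm`, simulates force cycles at four detection forces, re-detects
the blockage dwells and refits the kinetics:

```
F = 16.0 pN: <tau> =   4.26 s, k =  0.235 1/s (251 dwells, 40 censored)
F = 17.0 pN: <tau> =   2.50 s, k =  0.400 1/s (278 dwells, 14 censored)
F = 18.0 pN: <tau> =   1.49 s, k =  0.669 1/s (273 dwells, 1 censored)
F = 19.0 pN: <tau> =   1.08 s, k =  0.925 1/s (267 dwells, 0 censored)

Bell-Evans fit: k0 = 1.52e-04 1/s (injected 1e-04), Xdag = 1.90 +/- 0.11 nm (injected 2.0)
```

Mean dwell shortens with force; the slope of `ln k` vs `F` returns the
injected transition-state distance within its standard error and `k0`
within a factor ~1.5.  The other examples cover hairpin design
(`design_flat_hairpin.py`), binding-site location and motif probabilities
(`locate_binding_sites.py`), binding energy from hopping
(`hopping_binding_energy.py`) and footprints/recognition search
(`enzyme_footprint.py`).  A `unzipfoot` CLI wraps the same functions
(`design`, `simulate`, `analyze`, `kinetics`, `thermo`, `footprint`,
`run`).

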