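# leafletdyn

Leaflet-resolved flip-flop kinetics, pair statistics and ionophore-transport
quantification for bilayer-mimetic simulations and GUV (giant unilamellar
vesicle) assays.

## The problem

Ionophores carry metal ions across lipid membranes by diffusing between the
two bilayer leaflets. When several ionophore species share a membrane, their
mutual interactions can suppress each other's interleaflet transitions
("flip-flops") and shift their resting positions toward the membrane
periphery — which in turn throttles transport of the later-added species. In
GUV-based synthetic cells loaded with dormant apo-metalloenzymes
(urease/Ni²⁺, galactose oxidase/Cu²⁺, PLA₂/Ca²⁺), this cross-inhibition
makes the *order* of ionophore additions decide the cell's terminal fate.

`leafletdyn` packages the complete analysis chain for this system:

* **Flip-flop detection with hysteresis.** A molecule's membrane-normal COM
  position z(t) (z = 0 at the membrane centre, the mass-weighted centre of
  the phosphate reference particles) is reduced to its threshold excursions
  |z| ≥ d; every sign change in that subsequence is one confirmed transition.
  Defaults d = 0.7 nm (species A) and 0.6 nm (species B). Replica-averaged
  counts may be fractional.
* **Height distributions**, including the intensity-sensitive representation:
  of the two leaflet peaks of P(z), keep only the half with the higher
  maximum and re-histogram on |z|, optionally restricted to frames where two
  molecules share a leaflet.
* **Pair statistics**: lateral-2D and full-3D radial distribution functions
  g(r) with minimum-image distances and finite-N ideal-gas normalization,
  and distance-cutoff connected-component clustering.
* **Transport quantification** from fluorescence and area time series:
  per-GUV transport `(I_initial − I_final)/I_mean × 100`, Ca²⁺ relative
  transport `(I_final − I_initial)/ΔI_ref × 100`, plate-reader
  normalizations `(I_initial − I_x)/(I_initial − I_min) × 100` (quench) and
  `(I_x − I_initial)/(I_max − I_initial) × 100` (gain), dye retention
  `I_t/I_0 × 100`, and lysis calls from GUV area decay.
* **Fate logic**: the pluripotent → multipotent → terminal state machine
  (first ionophore commits the branch; the Ca-ionophore first is lysis and
  absorbing; a third input locks the state) and classification of fates from
  sensor readouts.
* **A ground-truthed synthetic generator**: overdamped Langevin solutes in a
  quartic double well U(z) = ΔE[(z/z0)² − 1]² with a Gaussian pair coupling
  that raises the mid-membrane barrier (ε) and biases paired solutes outward
  (κ), plus fluorescence/area trace generators — so every analysis is
  testable end-to-end against known truth.

## Worked example

```python
import numpy as np
from leafletdyn import (LangevinParams, PairInteraction, SimulationComposition,
                        simulate_solute_trajectories, ztraces_from_trajectory,
                        summarize_transitions, height_histogram, enumerate_fates)

params = LangevinParams(barrier_height=4.0, n_steps=100_000)  # 2 µs at 0.02 ns
free = SimulationComposition(counts={"A": 1, "B": 1})
paired = SimulationComposition(
    counts={"A": 1, "B": 1},
    interactions={("A", "B"): PairInteraction(epsilon=6.0, kappa=4.0)},
)

for name, comp in [("free", free), ("paired", paired)]:
    traces = {r: ztraces_from_trajectory(
                  simulate_solute_trajectories(params, comp, seed=r)[0])
              for r in range(4)}
    summary = summarize_transitions(traces)
    a = [tr for reps in traces.values() for tr in reps if tr.species == "A"]
    hist = height_histogram(a, mode="intensity_sensitive")
    print(f"{name:6s}  mean transitions per molecule: "
          f"A={summary.mean_count['A']:.2f} B={summary.mean_count['B']:.2f}   "
          f"|z| peak: {hist.peak_location():.3f} nm")

mapping, n = enumerate_fates()
print("terminal fates:", {"-".join(k): v for k, v in mapping.items()},
      "->", n, "distinct")
```

prints

```
free    mean transitions per molecule: A=52.75 B=66.00   |z| peak: 0.975 nm
paired  mean transitions per molecule: A=2.75 B=3.25   |z| peak: 1.125 nm
terminal fates: {'A-B-C': 'A-b', 'A-C-B': 'A-c', 'B-A-C': 'B-a', 'B-C-A': 'B-c',
                 'C-A-B': 'C', 'C-B-A': 'C'} -> 5 distinct
```

With the ε = 6 kT / κ = 4 kT·nm⁻¹ coupling switched on, flip-flop counts of
the very same solutes collapse by a factor of ~20 and the folded height
distribution's peak moves ~0.15 nm toward the head groups — the
interaction-induced suppression and peripheral shift that explain why a
previously added ionophore throttles its successors. The fate table shows
all six addition orders collapsing onto five distinct terminal fates, both
C-first orders ending in lysis.

A CLI mirrors the library:

```bash
leafletdyn run --config examples/demo.yaml --out out/      # full pipeline
leafletdyn fates                                           # fate table
leafletdyn transitions ztrace.tsv --threshold-a 0.7 --threshold-b 0.6
leafletdyn histogram ztrace.tsv --mode intensity_sensitive --out hist.tsv
```

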