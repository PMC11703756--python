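# Methods

## Transition detection

A flip-flop is scored only when residence in both leaflets is confirmed: the
z-trace is reduced to the subsequence of samples with |z| ≥ d, and every sign
change within that subsequence is one event. This is equivalent to a
two-state automaton with a dead zone (−d, d): crossings of z = 0 that never
reach the far-side threshold are recrossing noise and are ignored. The event
is timestamped at the first confirming sample in the new leaflet (the
criterion itself fixes no instant; the first confirmation is the earliest
defensible choice and makes events order-preserving under trace
concatenation). Confirmation distances default to 0.7 nm for species A and
0.6 nm for species B — close to those species' typical resting distance from
the bilayer centre — and must be given explicitly for anything else.

Consequences used as test invariants: inserting sub-threshold samples
anywhere cannot change the count; time reversal preserves the count and
flips directions; downsampling can only lose events, never create them.

Replica summaries average per-molecule counts across replicas, so fractional
means (e.g. 0.5 from counts 1 and 0 over two replicas) are expected. With
mixed observation lengths, rates are computed per replica and then averaged,
and a warning is logged.

## Height distributions

Two representations are provided. The full signed-z histogram is a plain
probability-per-bin normalization (bin width 0.05 nm by default, edges
aligned so z = 0 is an edge). The intensity-sensitive representation selects
the leaflet half whose peak bin is higher, keeps only that half's samples
and re-histograms them on |z|; the discarded half's share is retained as
`mass_share`. Exact peak ties break to the positive half — an arbitrary but
documented convention that only matters for perfectly symmetric data.
Same-leaflet conditioning keeps frames where both molecules have the same
instantaneous sign of z by default; a confirmed-leaflet (hysteresis-state)
variant is available, since "in the same leaflet" is underdetermined for
frames inside the dead zone.

## Pair statistics

g(r) is the ratio of observed minimum-image pair distances to the ideal
uniform expectation accumulated frame by frame from the pairs actually
considered; this makes the normalization finite-N correct (each reference
particle sees N−1 partners) and exact under leaflet conditioning, where the
eligible pair count varies per frame. The lateral-2D metric ignores z and
uses annulus areas over the box cross-section; the full-3D metric uses
spherical shells over the box volume with minimum image in all three
dimensions (exact for fully periodic calibration configurations; for
membrane systems z separations are far below half the tall box, so the z
minimum image is inert). r_max may not exceed the half-box of the chosen
metric. Clustering builds the contact graph at a distance cutoff (default
1.0 nm, the scale where solute–solute RDFs depart from unity) and takes
connected components per frame.

## The synthetic generator

The generator emulates the phenomenology the analyses target — two
metastable leaflet positions, rare interleaflet transitions, pair-induced
transition suppression, peripheral shifts, clustering — with an overdamped
Langevin model (Euler–Maruyama, units nm/ns/kT, kT ≡ 1):

* normal motion in U(z) = ΔE[(z/z0)² − 1]², minima at ±z0 (default 1.0 nm),
  barrier ΔE default 8 kT; lateral motion diffusive with periodic wrap;
* pair coupling U_ij = w(r_ij)[ε(G(z_i)+G(z_j)) − κ(|z_i|+|z_j|)], with
  w(r) = exp(−r²/2σ_r²) (σ_r default 1.0 nm, truncated at 3σ_r, minimum
  image) and G(z) = exp(−z²/2σ_z²) (σ_z default 0.5 nm). The ε term raises
  the mid-membrane barrier by ~ε·w when a partner is laterally close; the κ
  term tilts the wells outward by δ ≈ κ·w/U''(z0) = κ·w·z0²/(8ΔE) and, being
  r-dependent, binds pairs laterally by up to ≈ 2κz0 − 2εG(z0) at contact.
  Forces are exact gradients of the total energy, so lateral and normal
  dynamics share one energy surface; this single coupling reproduces all
  three observables (suppression, shift, clustering) at once. For the
  "paired" study condition ε = 6 kT and κ = 4 kT·nm⁻¹ are used: at ΔE = 4 kT
  these give a ~0.1 nm well shift and a few-kT contact binding, chosen from
  these formulas rather than fitted to any output.
* Euler–Maruyama is adequate because the dynamics is overdamped and the
  step-size guard (RMS single-step z displacement < z0/5, enforced at
  construction) keeps the drift term well resolved; the stationary
  z-distribution is verified against exp(−U)/Z by a KS test.
* Defaults: D_z = D_lat = 0.5 nm²/ns and dt = 0.02 ns. The diffusivity is a
  deliberately fast phenomenological scale: it makes spontaneous flip-flop
  well-sampled within the 2 µs synthetic runs (the Kramers rate at ΔE = 4 kT
  is ~0.03/ns) while leaving the barrier crossing rare on the step scale.
  The lateral box (6.3 nm) puts two solutes at the reference surface density
  of ~0.05 nm⁻².
* Two static sheets of "P" reference particles at ±1.9 nm are emitted with
  every trajectory so the analysis layer genuinely recomputes the membrane
  centre instead of trusting the generator's frame.

Ground truth (transition times by the same confirmed-excursion criterion,
leaflet occupancy, pair contact fraction at ≤1.5σ_r) is recorded at full
integration resolution, before frame striding.

What the generator does *not* emulate: atomistic lipid structure, solvent,
membrane undulations, orientation dynamics of real solutes, finite-size
membrane-centre fluctuations, or any calibrated free-energy surface — the
ε/κ coupling is an emulation target for the observed phenomenology, not a
claim about the real potential of mean force. Passing tests therefore
demonstrate that the *analysis chain* recovers known truth under the stated
phenomenology, not that the generator predicts any particular membrane.

## Transport quantification

The four normalizations are implemented exactly as defined in the module
docstring. I_initial and I_final are means over configurable windows
(default 3 samples) before the addition event and at the trace end, since
acquisition times vary between experiments; window 1 reduces to single
snapshots. Negative percentages are reported, not clipped (quench readouts
undershoot under noise); values outside [−5, 105] carry a QC flag. Dye
retention fixes the t = 0 sample as the 100 % baseline and matches requested
timepoints to the nearest sample within one sampling interval. Lysis calls
use a 3-point median filter and require the area to fall below half its
initial value *and stay below* until trace end; the onset is the first
sample of that terminal excursion.

## Fate logic

The state machine is deterministic: the first ionophore selects the branch
(A, B, or the absorbing lysed fate C), a distinct second ionophore selects
the dampened sub-fate (A-b, A-c, B-a, B-c), and any further input — or any
input to a lysed cell — leaves the label unchanged and marks the state
terminally locked. Re-adding an ionophore already in the history is rejected
rather than ignored, since it is not a defined experiment. Enumerating the
six orderings yields exactly five distinct terminal labels.

Readout classification partitions the (urease fold, oxidase fold, leakage,
lysed) space with config-exposed thresholds (defaults: fold ≥ 2 is "high",
leakage ≥ 20 % is "leaky"); because the leaky sub-fates genuinely overlap in
readout space, ambiguous panels (both branches high, neither high, or a
lysed flag alongside strong enzyme sensors) return an explicit
`unclassified` instead of a forced call.

## Problem sizes and numerical choices

The test suite and the acceptance script run 20-replica batteries of 2 µs
(10⁵ step) runs with 1–2 solutes — sizes at which every comparison
(suppression, shift, stationarity) resolves with non-overlapping 95 %
confidence intervals in seconds on one CPU. The detector–oracle equivalence
uses 10⁴ random traces of mixed length, threshold and autocorrelation. KS
tests thin trajectories to ~25 ns spacing so samples are effectively
independent, and use ΔE = 3 kT so both wells exchange many times per run.
RDF calibration uses 500 uniform random 40-particle configurations; per-bin
deviations are judged in Poisson SEM units of the ideal count.
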