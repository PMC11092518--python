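# Methods

This note documents the model and analysis choices behind `gridcan`: the
assumptions, the parameters that matter, what the synthetic inputs do and
do not emulate, and the numerical decisions a user should know before
trusting or extending the results.

## Model overview

The network implements the inhibition-stabilized continuous-attractor
hypothesis of grid-cell firing at spike level. Six populations interact:

- **MEC LII stellate cells** (the grid cells) receive all external and
  recurrent input and emit the spatial code being analyzed.
- **EC LI-II multipolar pyramidal cells** act as conjunctive
  (speed- and direction-tuned) cells, one per stellate, relaying the
  animal's velocity.
- **CA1 pyramidal cells** act as place cells with Gaussian firing fields
  tiling the arena; each projects to the stellate whose attractor phase
  corresponds to its field center, pinning the attractor state to the
  arena and correcting drift.
- **Three interneuron (IN) types** — axo-axonic, basket, and basket
  multipolar, all fast-spiking — mediate the only interaction between
  grid cells: stellate → IN excitation inside a small disc displaced
  along the stellate's preferred direction, and IN → stellate inhibition
  in an annulus. All wiring has uniform unit weights; there is no
  long-term plasticity.

Neuron dynamics use the nine-parameter Izhikevich model and synapses the
Tsodyks–Markram short-term-plasticity model with fast (AMPA/GABA_A) and
slow (NMDA/GABA_B) conductance channels; reversal potentials are
0 mV (both excitatory channels), −70 mV (GABA_A) and −90 mV (GABA_B),
with slow-channel decay fixed at the common simulator default of 150 ms
and a magnesium-block factor `((v+80)/60)² / (1+((v+80)/60)²)` on NMDA.
All neuron- and synapse-level constants are packaged in
`gridcan/data/tables.yaml` in pF/mV/pA/nS/ms units and are used verbatim.

## Sheet geometry and why the torus is twisted

Grid cells sit on an N × N sheet with periodic boundaries whose wrap
vectors are `e1 = (N, 0)` and `e2 = (N/2, N·√3/2)` — equal length, 60°
apart. The quotient is a *hexagonal* torus, so the linear arena-to-sheet
phase map `φ = s·R(θ)·x` (gain `s` = bump-lattice period / grid spacing,
orientation `θ`) sends each cell's firing locations to an equilateral
triangular lattice in the arena. A plain square torus would instead
yield square arena lattices — which the rotational grid score correctly
punishes with negative values — so the twist is what lets hexagonal
symmetry emerge from a finite periodic sheet. `twist=False` retains the
square torus for comparison.

Each scale preset fixes the bump-lattice period λ (the sheet holds
(N/λ)² bumps), the center-surround radii, the arena grid spacing and
orientation. The annulus radius tracks λ (pattern wavelength ≈ 1.6 ×
annulus radius), and the phase-map gain is chosen so the arena image
wraps the sheet approximately once: every stellate then receives direct
place-cell pinning when the animal crosses the matching part of the
arena. Presets:

| preset | sheet | bumps | spacing (cm) | role |
| --- | --- | --- | --- | --- |
| desk | 20×20 | 4 | 22 | reduced scale for tests/acceptance |
| intermediate | 40×40 | 4 | 22.5 | the connectivity-table configuration |
| small_low / small_high | 40×40 | 1 | 40 | low/high-rate small-scale mixture |
| large | 40×40 | 1 | 65 | ventral, large-scale mixture |

Interneuron counts follow the census values (834/833/833; 1200 each at
the large scale); since such counts do not fill a rectangle exactly, IN
sheets allow a partial final row and are scaled uniformly into stellate
coordinates. At the intermediate scale the wiring reproduces the printed
degree statistics (stellate→IN 12 ± 2 per type; IN→stellate 142 ± 66).
Distances are snapped to 1 nm-scale precision (1e-9 sheet units) before
radius comparisons so that lattice ties at an annulus boundary cannot
break asymmetrically on floating-point rounding.

## External drive

- **Conjunctive drive**: `I = I₀ + α·v·(1 + cos(ψ − θ_pref))/2` with the
  animal's speed `v` and heading `ψ`. Summed over the four cardinal
  preferences the tuning factor is exactly 2, so total network drive
  depends on speed only. Defaults (`I₀` = 300 pA, `α` = 10 pA/(cm/s))
  put conjunctive cells at ~15 Hz and stellates in the low single-digit
  range.
- **Place drive**: `I = A·exp(−‖x − c‖²/2σ²)`, σ = 5 cm (8 cm at the
  large scale), with 40 × 40 field centers tiling the arena. The
  CA1→stellate projection has out-degree exactly 1 through the phase
  map.
- **Noise**: independent Gaussian current noise (σ = 50–70 pA per step)
  on stellate and conjunctive cells. Besides realism this is load-
  bearing: identically parameterized, uncoupled neurons under identical
  drive are numerical clones and would spike in population-wide volleys,
  putting a large artificial harmonic comb into the population spectrum.
  For the same reason the engine starts every run with seeded uniform
  initial-voltage jitter in `[Vr, (Vr+Vt)/2]`.
- **Per-scale gain multipliers** on the four connection classes
  (conjunctive→stellate, CA1→stellate, stellate→IN, IN→stellate) absorb
  the scale dependence of in-degrees (e.g. the CA1 in-degree per
  stellate is ~4 at desk scale but ~1 at full scale). They were
  calibrated once per preset so that (i) bumps form and track, (ii)
  stellate mean rates land in the observed low-single-digit range, and
  (iii) the network sits in the weak-coupling rhythm regime; they are
  stored as named config constants.

## Simulation engine

Forward Euler at dt = 0.5 ms with the voltage advanced in two half-steps
per step; spike events and conduction use a fixed 1-ms delay; TM state
and conductances decay by exact exponential factors. Within a step the
order is: decay → deliver delayed releases → external drive → currents →
neuron update → queue releases → log. A 500-ms settle phase (zero
velocity, place input at the start position, a 200-pA/100-ms broad
excitation pulse to nucleate bumps) precedes playback and is excluded
from all analysis. Voltages are clamped below at −100 mV: no receptor
reversal lies below −90 mV, so the floor only guards the quadratic
voltage term against Euler overshoot under extreme hyperpolarizing
conductance.

Two numerically identical backends exist: a vectorized numpy reference
built directly from the module-level operations, and a numba kernel
(default, ~5–10× faster) that the tests cross-check against the
reference. Runs are bit-deterministic given (config, trajectory, seed);
the two backends use different noise streams, so they agree in
statistics rather than in individual spike times.

## Synthetic foraging trajectories

The generator emulates random foraging in the 45 × 45 cm arena: a
wrapped-Gaussian heading random walk (persistence 0.97 at 50 Hz), an
AR(1) speed fluctuation around a 12 cm/s mean (floored at 0, capped at
the 90 cm/s tracking-outlier ceiling), and reflective walls. Ten minutes
of synthesis visits every 3-cm bin of the arena. It does **not** emulate
wall-following or thigmotaxis, reward-directed runs, rest bouts, or
head-direction/body-orientation dissociation; passing tests therefore
show that the network tracks *statistically homogeneous* exploration,
not that it reproduces behavior-specific occupancy biases of real
sessions.

## Analysis conventions

- Rate maps: 3-cm bins; Gaussian smoothing (σ = 3 cm) applied to spike
  counts and occupancy separately before division; unvisited bins stay
  NaN and are excluded (zero-filling inflates grid scores).
- Autocorrelograms: Pearson correlation per 2-D lag over mutually
  visited bins, lags with < 20 overlapping bins masked.
- Grid score: annulus from the central peak's first zero crossing
  outward, score = min(corr at 60°, 120°) − max(corr at 30°, 90°, 150°),
  maximized over outer radii; only radii whose full lag ring is defined
  participate (partially masked rings would bias the 90° rotation on the
  square lag domain). Scores ≥ 0.2 count as acceptable grids.
- Fields: connected components above 20% of the map peak, at least 9
  bins, and no more than half the visited area (larger components are
  background, so a uniform map has no fields); size = equal-area circle
  diameter.
- Spacing: median distance from the center to the six nearest
  autocorrelogram peaks. When the grid spacing approaches the box size
  the peak ring falls outside the ±42-cm measurable lag range (as it
  does for real ~45-cm-spacing cells recorded in the same box), and the
  estimator falls back to nearest-neighbor distances between rate-map
  field centers.
- Spectra: 1-ms population rate, 3-ms Gaussian smoothing, mean removed,
  multitaper PSD (time-bandwidth 3, 5 DPSS tapers, 10-s segments
  averaged); band shares over 1–100 Hz with delta 1–4, theta 4–12, beta
  12–25, gamma 25–100 Hz.
- Phase coupling: reference rate band-passed (4th-order zero-phase
  Butterworth) around its in-band spectral peak ± 4 Hz, analytic-signal
  phase, MRVL = |mean unit phase vector|, Rayleigh significance via
  Zar's large-n approximation (cross-checked against an independent
  circular-statistics implementation in the tests).

## Parameter sweeps

`gridcan.sweep` varies a pair of stellate Izhikevich parameters or of
stellate→IN TM parameters (applied jointly to all three IN connections)
over 9 × 9 grids spanning ±50% of the table values (nine values per
axis, base value included; the reset voltage is also addressable by its
plot alias "V_min"). Every grid point reruns the same seeded trajectory
at the desk scale and scores a probed stellate; failures are recorded as
NaN, never silent zeros. Biologically realistic windows (the teal
regions) are shipped as editable relative half-widths in the config —
the experimental firing-pattern fits they derive from require raw
electrophysiology traces that are out of scope here.

Depression recovery (tau_x) is the clearest sensitivity: multiplying it
by 8 on the stellate→IN connections depresses those synapses into
silence, removes the center-surround inhibition, and collapses the grid
(score below 0.2 with widespread firing at similar mean rate), while
dividing it by 8 leaves the grid intact — the viable range is narrow and
asymmetric.

## Problem sizes used by the packaged checks

The test suite and the acceptance script run the desk preset (20×20
stellate sheet, 209/208/208 INs) on 1–5-minute synthetic trajectories,
and the full-scale multi-scale mixture (three 40×40 runs, 29 scored
cells) on a 5-minute trajectory; these sizes give stable statistics for
the quantities checked while keeping a complete run in the minutes
range on one CPU.

## Known limitations

- Spike-phase coupling in the model is weak but not as weak as in the
  recordings it emulates: stellate beta MRVL measures ~0.07 here against
  the reported 0.04, and the beta share of combined MEC LII power runs
  ~45–55% against 41.7%, with the correct beta > gamma ordering. The
  model's beta rhythm is generated almost entirely by the E–I loop and
  the periodic conjunctive relay, which couples these two observables;
  real tissue has additional desynchronizing heterogeneity that the
  uniform parameter tables do not represent.
- Place pinning concentrates extra firing in one field relative to its
  lattice siblings (visible in single-cell maps), an acknowledged
  consequence of single-pathway drift correction.
- No head-direction ring, boundary cells, theta-rhythm speed code, or
  learned connectivity; the conjunctive speed-control function is a
  documented linear-cosine substitute, and fast-to-slow speed
  transitions are handled only by the velocity smoothing window.
- Large-scale (65-cm spacing) cells rarely show two complete fields in
  the 45-cm arena, so their spacing is unmeasurable in-box and they
  contribute only rates and field sizes to the mixture statistics.
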