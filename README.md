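# gridcan

A spiking continuous-attractor network (CAN) model of medial entorhinal
cortex (MEC) layer II grid cells, with the complete analysis stack used
to characterize grid-cell physiology: spatial rate maps, autocorrelograms
and grid scores, field size and spacing, population spectra, spike-phase
coupling, and parameter-robustness sweeps.

## Who this is for

Computational neuroscientists studying spatial coding who want a
data-driven, spike-level implementation of the CAN hypothesis: six neuron
populations (MEC LII stellate grid cells, EC LI-II multipolar pyramidal
conjunctive cells, CA1 pyramidal place cells, and three perisomatic
interneuron types) with published excitability and synaptic constants,
wired so that hexagonal firing patterns *emerge* from network dynamics
during simulated foraging in a 45 × 45 cm arena.

## The model

**Neurons** follow the nine-parameter Izhikevich formalism

```
C dv/dt = k (v − Vr)(v − Vt) − u + I        v ≥ Vpeak → v ← c,  u ← u + d
  du/dt = a (b (v − Vr) − u)
```

with per-type constants (capacitance, rest/threshold voltages, spike
cutoff and reset, recovery dynamics) taken from published fits for each
neuron type (fast-spiking constants for the three interneuron types).

**Synapses** use the Tsodyks–Markram short-term-plasticity model: on each
presynaptic spike `u ← u + U(1−u)`, release `R = u·x`, `x ← x − R`, and
the fast (AMPA/GABA_A) and slow (NMDA/GABA_B) conductances of the targets
are incremented by `g·w·R`; between spikes `u → 0`, `x → 1`, and the
conductances decay exponentially. Currents are Ohmic,
`I = Σ s·(E_rev − v)`, with a voltage-dependent magnesium block on the
NMDA channel.

**Network**: grid cells live on a twisted (hexagonal) torus and interact
only through inhibition — each stellate excites interneurons inside a
small disc displaced along the cell's preferred direction (N/E/S/W), and
each interneuron inhibits stellates in a surrounding annulus. This
center-surround structure carves the population activity into bumps;
velocity-tuned conjunctive input moves the bumps as the animal runs, and
Gaussian place-field input from CA1 pins the bump phase to the arena,
correcting drift. Each cell therefore fires on a hexagonal lattice of
arena locations; grid spacing and field size follow from the scale
preset (`small_low`, `small_high`, `intermediate`, `large`, plus a
reduced `desk` preset for laptop-scale work).

## Worked example

```python
from gridcan.engine import SimConfig, run_simulation, Network, STELLATE
from gridcan.stimulus import synthesize_trajectory
from gridcan.spatial import grid_metrics

traj = synthesize_trajectory(300.0, seed=3)        # 5 min of foraging
cfg = SimConfig(preset="desk", seed=1)
result = run_simulation(cfg, traj)

layout = Network(cfg).layouts[STELLATE]
spikes = result.spikes.cell_spike_times_s(STELLATE, layout.center_index())
gm = grid_metrics(spikes, traj)
print(f"grid score {gm.score:.2f}  mean rate {gm.mean_rate:.2f} Hz  "
      f"spacing {gm.spacing_cm:.1f} cm")
```

prints (exact numbers vary slightly with seeds):

```
grid score 1.01  mean rate 2.80 Hz  spacing 27.7 cm
```

A score above 0.2 marks an acceptable grid pattern; the mean rate sits in
the low single-digit range typical of grid cells, and the spacing
reflects the desk preset's ~22-cm design scale (sampling and smoothing
bias the peak-based estimate slightly upward).

The same pipeline is available from the shell:

```bash
gridcan synth-traj --duration 300 --seed 3 --out traj.csv
gridcan simulate --preset desk --traj traj.csv --seed 1 --probe 10 10 --out run.h5
gridcan analyze run.h5 --traj traj.csv --cell 10 10
gridcan sweep --pair b,d --preset desk --out sweep.csv
```

## Layout

| module | contents |
| --- | --- |
| `gridcan.izhikevich` | neuron dynamics, population factory |
| `gridcan.synapses` | TM plasticity, conductance channels, receptor currents |
| `gridcan.topology` | sheet layouts, preferred directions, CS wiring, phase map |
| `gridcan.stimulus` | trajectory synthesis/IO, velocity, conjunctive and place drive |
| `gridcan.engine` | closed-loop simulation (numpy reference + numba backend) |
| `gridcan.spatial` | rate maps, autocorrelograms, grid score, fields |
| `gridcan.rhythms` | population rates, multitaper spectra, spike-phase coupling |
| `gridcan.sweep` | 9 × 9 parameter-robustness sweeps |
| `gridcan.io`, `gridcan.plots`, `gridcan.cli` | HDF5 archives, figures, CLI |

See `docs/methods.md` for the modeling choices, parameters and known
limitations.
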