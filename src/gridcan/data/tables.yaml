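# Neuron excitability (9-parameter Izhikevich), synaptic (Tsodyks-Markram)
# and network-preset constants for the MEC grid-cell attractor model.
#
# Units: C pF, voltages mV, a 1/ms, b nS, d pA, conductances nS, taus ms.
# Population keys and connection keys are the canonical neuron-type names.

populations:
  "MEC LII Stellate":
    count: 1600
    C: 118.0
    k: 0.62
    Vr: -58.53
    Vt: -43.52
    a: 0.005
    b: 11.69
    Vpeak: 11.48
    Vreset: -49.52
    d: 0.0
  "EC LI-II Multipolar Pyramidal":
    count: 1600
    C: 375.0
    k: 0.37
    Vr: -70.53
    Vt: -39.99
    a: 0.001
    b: 0.01
    Vpeak: 3.96
    Vreset: -54.95
    d: 7.0
  "CA1 Pyramidal":
    count: 1600
    C: 530.0
    k: 1.74
    Vr: -69.98
    Vt: -57.43
    a: 0.003
    b: -0.782
    Vpeak: 24.45
    Vreset: -60.35
    d: 25.0
  "EC LII AxoAxonic":
    count: 834
    C: 20.0
    k: 1.0
    Vr: -55.0
    Vt: -40.0
    a: 0.15
    b: 8.0
    Vpeak: 25.0
    Vreset: -55.0
    d: 200.0
  "MEC LII Basket":
    count: 833
    C: 20.0
    k: 1.0
    Vr: -55.0
    Vt: -40.0
    a: 0.15
    b: 8.0
    Vpeak: 25.0
    Vreset: -55.0
    d: 200.0
  "EC LII Basket Multipolar":
    count: 833
    C: 20.0
    k: 1.0
    Vr: -55.0
    Vt: -40.0
    a: 0.15
    b: 8.0
    Vpeak: 25.0
    Vreset: -55.0
    d: 200.0

# Fast channels are AMPA / GABA_A; slow channels are NMDA / GABA_B.
# Slow-channel decay uses the common simulator default of 150 ms.
connections:
  "EC LI-II Multipolar Pyramidal to MEC LII Stellate":
    g_fast: 11.627
    tau_d_fast: 3.380
    U: 0.180
    tau_u: 49.920
    tau_x: 152.856
    g_slow: 7.126
    tau_d_slow: 150.0
  "MEC LII Stellate to EC LII AxoAxonic":
    g_fast: 1.050
    tau_d_fast: 3.085
    U: 0.167
    tau_u: 49.920
    tau_x: 167.686
    g_slow: 0.644
    tau_d_slow: 150.0
  "MEC LII Stellate to MEC LII Basket":
    g_fast: 1.050
    tau_d_fast: 2.887
    U: 0.167
    tau_u: 49.920
    tau_x: 152.857
    g_slow: 0.644
    tau_d_slow: 150.0
  "MEC LII Stellate to EC LII Basket Multipolar":
    g_fast: 1.050
    tau_d_fast: 2.641
    U: 0.197
    tau_u: 49.920
    tau_x: 136.570
    g_slow: 0.644
    tau_d_slow: 150.0
  "EC LII AxoAxonic to MEC LII Stellate":
    g_fast: 0.626
    tau_d_fast: 4.561
    U: 0.145
    tau_u: 27.306
    tau_x: 420.838
    g_slow: 0.383
    tau_d_slow: 150.0
  "MEC LII Basket to MEC LII Stellate":
    g_fast: 0.626
    tau_d_fast: 4.488
    U: 0.151
    tau_u: 27.810
    tau_x: 443.499
    g_slow: 0.383
    tau_d_slow: 150.0
  "EC LII Basket Multipolar to MEC LII Stellate":
    g_fast: 0.626
    tau_d_fast: 4.948
    U: 0.162
    tau_u: 30.543
    tau_x: 382.485
    g_slow: 0.383
    tau_d_slow: 150.0
  "CA1 Pyramidal to MEC LII Stellate":
    g_fast: 9.248
    tau_d_fast: 3.380
    U: 0.123
    tau_u: 49.710
    tau_x: 153.400
    g_slow: 5.668
    tau_d_slow: 150.0

receptors:
  E_fast_exc: 0.0
  E_slow_exc: 0.0
  E_fast_inh: -70.0
  E_slow_inh: -90.0

arena:
  side_cm: 45.0
  sample_rate_hz: 50.0
  speed_ceiling_cm_s: 90.0

# Scale presets. Sheet units: one stellate-grid spacing on the (twisted)
# hexagonal torus. `spacing_cm` is the arena grid spacing the preset targets;
# `bump_lattice` is the sheet-space period of the bump pattern; CS radii are
# in sheet units. `gain` entries are per-scale synaptic gain multipliers.
presets:
  intermediate:
    stellate_sheet: [40, 40]
    in_counts: [834, 833, 833]
    bump_lattice: 20.0
    cs_inner: 11.4
    cs_outer: 13.0
    cs_disc_radius: 2.52
    direction_offset: 2.0
    spacing_cm: 22.5
    orientation_deg: 15.0
    gain: {e2i: 6.0, i2e: 8.0, conj: 4.0, place: 3.0}
    drive: {I0: 300.0, alpha: 10.0, A_place: 300.0, sigma_place: 5.0}
    noise_sigma: 50.0
  small_low:
    stellate_sheet: [40, 40]
    in_counts: [834, 833, 833]
    bump_lattice: 40.0
    cs_inner: 6.0
    cs_outer: 23.0
    cs_disc_radius: 2.9
    direction_offset: 2.0
    spacing_cm: 40.0
    orientation_deg: 15.0
    gain: {e2i: 6.0, i2e: 0.6, conj: 4.0, place: 16.0}
    drive: {I0: 260.0, alpha: 9.0, A_place: 300.0, sigma_place: 5.0}
    noise_sigma: 50.0
  small_high:
    stellate_sheet: [40, 40]
    in_counts: [834, 833, 833]
    bump_lattice: 40.0
    cs_inner: 6.0
    cs_outer: 23.0
    cs_disc_radius: 2.9
    direction_offset: 2.0
    spacing_cm: 40.0
    orientation_deg: 15.0
    gain: {e2i: 6.0, i2e: 0.6, conj: 5.0, place: 22.0}
    drive: {I0: 340.0, alpha: 11.0, A_place: 340.0, sigma_place: 5.0}
    noise_sigma: 50.0
  large:
    stellate_sheet: [40, 40]
    in_counts: [1200, 1200, 1200]
    bump_lattice: 40.0
    cs_inner: 8.0
    cs_outer: 23.0
    cs_disc_radius: 1.4
    direction_offset: 2.5
    spacing_cm: 65.0
    orientation_deg: 15.0
    gain: {e2i: 6.0, i2e: 0.6, conj: 4.0, place: 12.0}
    drive: {I0: 300.0, alpha: 10.0, A_place: 300.0, sigma_place: 8.0}
    noise_sigma: 50.0
  desk:
    stellate_sheet: [20, 20]
    in_counts: [209, 208, 208]
    bump_lattice: 10.0
    cs_inner: 5.3
    cs_outer: 7.0
    cs_disc_radius: 2.0
    direction_offset: 1.5
    spacing_cm: 22.0
    orientation_deg: 15.0
    gain: {e2i: 4.0, i2e: 6.0, conj: 4.0, place: 3.0}
    drive: {I0: 300.0, alpha: 10.0, A_place: 300.0, sigma_place: 5.0}
    noise_sigma: 70.0

# Biologically realistic windows used by the parameter sweep (the teal
# regions): relative half-widths around the table values above. Editable
# config constants; the underlying experimental fits are not recomputed here.
realism_bounds:
  im_rel: 0.25
  tm_rel: 0.40
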