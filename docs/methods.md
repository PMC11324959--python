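# Methods

`striatonet` models the isolated striatum as a spatial network of
conductance-based neurons and asks two questions: how does reduced
cortico-striatal drive reshape the network's macroscopic activity, and
which deep-brain-stimulation (DBS) parameters best restore the healthy
pattern.  This note records the model, the defaults, their provenance, and
the choices made where the design was genuinely open.

## Geometry

The network lives on a synthetic 3-D point cloud standing in for
atlas-derived neuron coordinates: two disjoint ellipsoids in an MNI-like
frame (mm), a caudate-like volume (centre (-11, 6, 8), semi-axes
(5.5, 18, 9.5)) and a larger putamen-like volume (centre (8, -2, -4),
semi-axes (7.5, 16, 12)), together ~10 cm^3 — gross single-hemisphere
striatal scale.  1,995 points are placed by uniform rejection sampling,
split between nuclei in proportion to volume; 5% (99 cells, floor
rounding) are labelled fast-spiking (FS) interneurons uniformly at random,
the rest medium spiny neurons (MSN).

The density (~0.2 points/mm^3) is a modelling constraint, not an
anatomical one: the wiring rule needs at least 20 (MSN) and ideally 100
(FS) candidates inside a 5 mm ball, which fixes the volume given N.
Near the surface a ball is truncated, so some boundary FS cells find fewer
than 100 candidates and connect to all of them (counted and warned, never
silent).  Reduced networks (e.g. the 500-neuron configuration used for
fast runs and the sensitivity study) rescale the ellipsoids by
(N/1995)^(1/3) so the local densities — and hence per-neuron input
statistics and firing rates — are preserved.

What the synthetic cloud deliberately does *not* reproduce is the strong
density heterogeneity and curvature of the real nuclei (e.g. the thin
caudate tail).  Several graph observables are sensitive to exactly that
heterogeneity; see "Known limitations".

## Connectome

Directed adjacency A with A[i, j] = 1 meaning neuron j innervates neuron
i.  Each MSN emits k = 20 edges to targets drawn uniformly from its 5 mm
ball; each FS emits k = 100 the same way.  Independently, for every local
edge, with probability p = 0.05 one extra edge to a uniformly chosen
*remote* node (outside the ball) is added — an additive small-world
variant (no rewiring removal), so E[out-degree] = k(1 + p).  Multi-edges
and self-loops are excluded.  MSN→FS feedback arises implicitly whenever a
sampled target happens to be an FS cell; no extra rule is invented.

Graph measures (mean shortest path, global efficacy with 1/inf = 0,
clustering, unnormalised betweenness over unordered pairs) are computed on
the symmetrised union graph; only the degree distribution is reported for
directed out-edges, which the construction rule controls.  Community
detection is recursive spectral bisection of the modularity matrix
(leading-eigenvector sign, Kernighan–Lin fine-tuning pass), accepting a
split only if it raises Q and both sides keep at least 180 members; Q of
the returned partition always equals the direct definition evaluated on
the assignment.

## Neuron and synapse models

MSNs carry fast Na (m^3 h), delayed-rectifier K (m^4), leak, and a slow
non-inactivating M-type K current (m^1); FS cells carry fast Na with
instantaneous activation (m_inf^3 h), Kv3-type K (n^2), leak, and the
D-type K current (m^3 h, tau_m = 2 ms, tau_h = 150 ms) that delays firing
onset.  All synapses are GABAergic: a presynaptic gate
ds/dt = alpha(1-s)H(V) - beta*s with H(V) = 1 + tanh(V/10), alpha = 4 and
beta = 1/13 ms^-1 (MSN sources) or 1/11 ms^-1 (FS sources); the
postsynaptic current is g_XY (V - E_GABA) * sum_j A_ij s_j with
E_GABA = -80 mV, conductances split by presynaptic/postsynaptic class.

Parameter provenance is tracked in three tiers:

* **printed** (fixed): E_GABA, alpha/beta, the drive levels I0 = 5
  (healthy) and 1.5 (abnormal) uA/cm^2, and the sensitivity intervals
  I0 in [1.5, 5], g_MM in [0, 0.1].
* **inherited** (from the predecessor MSN/FS models whose rate functions
  this package reproduces): C = 1 uF/cm^2; MSN g_Na/g_K/g_leak/g_M =
  100/80/0.1/1.3 mS/cm^2, E_Na/E_K/E_leak = 50/-100/-67 mV; FS
  g_Na/g_Kv3/g_leak/g_D = 112.5/225/0.25/0.39, E_Na/E_K/E_leak =
  50/-90/-70 mV; FS gate time constants (tau_h, tau_n voltage-dependent;
  D-current constants above).
* **chosen** (unprinted anywhere; this package's calibration): the four
  coupling conductances g_MM = 0.003, g_FM = 0.033, g_FF = 0.01,
  g_MF = 0.002 mS/cm^2, and the DBS defaults below.  The couplings were
  set once, on 500-neuron calibration runs, so that the two printed drive
  levels reproduce the reported regime behaviour as closely as this
  geometry allows (high tonic rate with gamma-band rhythm at I0 = 5;
  ~15 Hz with low-frequency-shifted spectrum at I0 = 1.5).  FS→MSN
  coupling an order of magnitude above MSN→MSN matches striatal
  physiology, where feed-forward FS inhibition on the soma is far stronger
  than distal MSN collateral inhibition.

Two printed formulas required a judgement call:

* The M-current rate functions are printed identically to the fast-K
  rates.  Taken literally, the M-current becomes a fast K-like current and
  the single-MSN f–I curve acquires a hard onset near I0 ≈ 4.5, leaving
  the whole network silent at the abnormal drive 1.5 — the printed
  abnormal regime (≈15 Hz) is then unreachable in a purely inhibitory
  network.  The default therefore uses the predecessor model's slow
  M-current kinetics (f(1.5) ≈ 22 Hz, f(5) ≈ 88 Hz, matching both printed
  regimes); `MSNParams(m_current_kinetics="as_printed")` restores the
  literal reading.
* The FS Na-inactivation steady state is printed with a sign that makes
  h_inf *increase* with depolarisation.  It is implemented as printed
  (default); `FSParams(h_inactivating=True)` restores the conventional
  inactivating sigmoid.  A useful consequence of the printed form is an FS
  rheobase of ≈3 uA/cm^2, which places the collapse of gamma-band
  activity at I0 ≈ 3 — exactly where the reported collapse sits.

## DBS

I_DBS(x, t) = A * exp(-|x - x0|^2 / sigma^2) * pulse(t), where pulse is
the product of step functions of two shifted sinusoids: on during
(T/2 - delta, T/2) of each period T = 1000/f (duty cycle delta/T).
Defaults: delta = 1 ms, sigma = 10 mm, both config-exposed and echoed into
every artefact.  Neither value is printed; sigma = 10 mm was chosen
because the stimulation must plausibly reach most of one nucleus: with the
reported optimal amplitude (~195 uA/cm^2) a 2 mm spread would drive only a
few percent of the cells, which cannot produce the reported broad
activation, restored ~90–100 Hz rate, or a synchronisation index of ~0.67
(roughly two thirds of the population phase-locked).  Amplitude units are
taken as uA/cm^2 since I_DBS adds directly to the applied current.

## Integration and spike detection

Fixed-step RK4 on all states (membrane potentials, HH gates, synaptic
gates), dt = 0.05 ms for production runs and 0.01–0.05 ms in fixtures;
initial V ~ U(-80, -50) mV (seeded), gates at their steady state for that
voltage, s = 0.  Gates are audited each step: excursions beyond [0, 1] by
more than 1e-6 (far above the RK4 truncation error) abort the run; smaller
ones are clipped.  Spikes are strict upward crossings of -15 mV with a
1 ms lockout to avoid double counts on coarse grids.  Halving dt changes
healthy-regime spike counts by well under 2%.  Optional zero-mean membrane
noise exists but defaults to off.

## Biomarkers

* Mean network activity: population spike count per 10 ms window, divided
  by the 100 0.1-ms bins, times 10,000, divided by N — i.e. spikes per
  neuron per second; its time average equals total spikes/(N * duration)
  exactly.
* Mean voltage V-bar and its power spectrum |X(f)|^2 (mean removed, zero
  padded to 0.01 Hz partitioning, optional Gaussian smoothing of width
  2 Hz); frequencies are reported in Hz.  Spectra of regime runs discard
  the first 200 ms (initial-condition transient).
* Gamma band fraction: trapezoidal area in [30, 80] Hz over [0, 300] Hz.
* Phase synchronisation r_sync(t): modulus of the mean unit phasor, with
  each neuron's phase interpolated linearly between consecutive spikes.
  Neurons without a defined phase at t (fewer than two spikes, or t outside
  their first–last spike span) are excluded and the divisor renormalised —
  including them at phase 0 would fabricate synchrony in sparse regimes.
  r is reported only where at least 10% of the population has a phase.

## Objectives and optimisation

Phi1 = L1 distance of mean-activity traces over [0, 1] s; Phi2 = L1
distance of power spectra over [0, 300] Hz; Phi3 = Phi1 + gamma * Phi2.
The optimiser searches r = (x0, y0, z0, A, f) within bounds (electrode
inside the cloud's bounding box, A >= 0, f in (1, 300] Hz) by
re-simulating the abnormal network per candidate with a common seed, in a
residual-vector trust-region least-squares mode (default) or a
derivative-free Nelder–Mead scalar mode; solver settings: step tolerance
1e-3, function tolerance 0.1, at most 100 iterations, optional
multi-start.  Blow-ups at a candidate score +inf and the search continues.
For Phi3, gamma is selected from a geometric schedule {1, 1/2, 1/4, ...}
by the user; the package does not hide an automatic schedule behind the
API because each step costs a full simulation campaign.

## Sensitivity analysis

The windowed firing rate (10 ms bins over 200–400 ms) is expanded in a
Legendre polynomial chaos over uniform inputs mapped to [-1, 1]^d:
total-degree truncation at p = 3 (10 basis terms for d = 2), coefficients
by pseudo-spectral projection on the full Gauss–Legendre tensor grid with
(p+1)^d = 16 nodes, one simulation per node with a common seed.  Sobol
indices follow from coefficient norms: S_u = (sum of c_n^2 <Psi_n, Psi_n>
over terms active exactly in u) / total variance, per bin and
time-averaged over non-degenerate bins.  The implementation is validated
against analytic ANOVA decompositions (additive models, the Ishigami
function) and a quasi-Monte-Carlo Saltelli estimator.

## Problem sizes

Production-scale quantities are computed on the 1,995-node network with
1 s simulations at dt = 0.05 ms (about 45 s each on one core); the test
suite and the sensitivity study use 500-neuron density-matched networks,
which preserve per-neuron rates to within a few percent of the full-size
runs.

## Known limitations

* Uniform point density inside convex ellipsoids is the largest
  idealisation.  On this geometry the constructed network is more
  homogeneous than its atlas-based counterpart: the mean shortest path
  settles near 2.8–3 (reported: ~4), MSN clustering near 0.29–0.31
  (reported: 0.22), and identical neurons with near-identical in-degrees
  synchronise more readily, inflating the DBS-state r_sync toward ~1
  (reported maximum: 0.67).
* In the healthy regime the spectral peak of V-bar tracks the MSN firing
  rate; the reported combination of a 90 Hz mean rate with a 65 Hz
  spectral peak and 0.9 gamma fraction does not emerge here, and appears
  to require heterogeneity (in rates and inputs) that the uniform cloud
  cannot supply.  The qualitative contrast between regimes — gamma-band
  dominated versus low-frequency dominated, with the collapse near
  I0 ≈ 3 — is robust.
* Single-compartment neurons, no dopamine receptor kinetics, no
  plasticity, no cortical/thalamic partners; V-bar is only a coarse LFP
  proxy.
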