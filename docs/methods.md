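# Methods

## The kinetic model

Permeation is modelled as a continuous-time Markov chain on a single cycle
of ion-occupancy states. Forward transitions connect consecutive states in
order, the last closing back on the first; one full traversal transports
net one ion. Each transition carries an exponential voltage law

    k_ij(V) = k_ij(0) · exp(d_ij · e·V / k_B·T),

i.e. `k0 · exp(d·V/V_T)` with the thermal voltage `V_T = k_B·T/e`
(25.852 mV at the 300 K default; temperature is configurable). `d` is the
electrical distance: the fraction of the applied field the step's underlying
motion traverses. It is unrestricted in sign — steps that the field opposes
have `d < 0`.

Cycles are unidirectional by default: the reference parameterizations list
forward rates only, and the analysis (rate ranking, bottleneck class) only
needs those. Backward transitions can be supplied explicitly, each reversing
one forward edge with its own `(k0, d)`; the steady-state solver and flux
handle them throughout. A consequence of the forward-only idealization is a
nonzero cycle flux at `V = 0`; the model i-V curve of a unidirectional cycle
therefore does not pass through the origin and is a rate-comparison tool,
not a quantitative current predictor near 0 mV.

Sign convention: positive voltage drives the cycle in its forward direction.
Units project-wide: rates ns⁻¹, voltage mV, current pA, time ns. A flux of
1 ion/ns equals `e/ns` = 160.218 pA; 200 mV across a monovalent charge is
4.6 kcal/mol.

The stationary distribution solves `πQ = 0` via the null space of `Qᵀ`
(degeneracy tolerance 1e−10), normalized to sum 1; a null space of dimension
≠ 1 (reducible or degenerate generator) is an error, not a silent pick.
For unidirectional cycles this reduces to the closed forms `P_i ∝ 1/k_i`
and `J = [Σ_i 1/k_i]⁻¹`, which the tests use as an independent oracle
against the general solver.

## Synthetic trajectories

The trajectory generator replaces the original atomistic simulations as the
data source. Its defaults are the reference ensemble design: five voltages
(100, 200, 400, 600, 800 mV), 100 trajectories per voltage, 10 ns each —
1 μs of data per voltage per cycle.

Sampling is exact and event-driven: dwell times are exponential with the
state's total exit rate, successors drawn proportionally to outgoing rates.
For unidirectional cycles the state sequence is deterministic, so dwells are
drawn in vectorized blocks and truncated at the horizon; cycles with
backward transitions use a per-event loop. Both paths are exact samplers of
the chain (they consume randomness differently, so bit-level reproducibility
holds per topology). The start state is drawn from the stationary
distribution by default — the chain analogue of equilibrating before
production, avoiding burn-in bias in dwell statistics — or can be fixed by
label. Per-trajectory seeds derive from the master seed as
`SeedSequence(master, spawn_key=(voltage_index, trajectory_index))`, a
stable, collision-safe realization of hashing the three indices together.

A permeation event is logged at each firing of the cycle's designated
permeation transition (the cycle-closing edge for the bundled cycles). At
steady state every edge of a unidirectional cycle fires equally often, so
the event rate is invariant to which edge is designated.

What the surrogate does *not* emulate: failed entry attempts, spatial
coordinates, water, and the diffusive approach of ions to the entrance (the
approach rate enters only as the scalar `n_appr` in the diffusion-limit
comparison). Passing tests therefore validate the estimation and
classification machinery on data that exactly obeys the model's
assumptions; they do not show that real trajectories are Markovian or that
dwells are exponential.

## Rate estimation and voltage fits

The estimator is the counting relation `J_ij = k_ij·P_i` in its exact
per-dwell form `k_ij = N_ij / T_i` (the total simulation time cancels
algebraically between `J_ij = N_ij/T_total` and `P_i = T_i/T_total`; a
property test asserts the identity). Counts are pooled over the ensemble at
each voltage — equivalent to per-trajectory averaging for long totals, and
better behaved for rarely visited states. Truncated final segments
contribute dwell time but no transition, the correct treatment of censored
exponential dwells. A transition never observed at a voltage is an explicit
missing value, not a zero rate. The dispersion model is Poisson, `k/√N`.

Voltage dependence is fitted per transition by unweighted ordinary least
squares on `(V, ln k)`; `d = slope·V_T`, `k0 = exp(intercept)`. Unweighted
is the default because the fit is a first-approximation summary, not a
maximum-likelihood estimate; a `√N`-weighted variant is available behind a
flag. All five voltages enter the fit and `k0` is an extrapolation to 0 mV.
Voltages with missing estimates are dropped; fewer than two usable points
yields a reported non-fit, never an imputed one.

## i-V analysis

**Shape.** Physical i-V curves pass through the origin, so curvature is
probed by the chord slope `i/V`: monotonically decreasing chords → sublinear,
increasing → superlinear. A curve whose points all lie within a relative
tolerance (default 5%) of the best origin-anchored line is linear; anything
else is mixed/undetermined. The reported statistic is the signed mean
relative deviation from that origin-anchored line. The verdict is invariant
under separate rescaling of either axis.

**Bottleneck.** The rate-limiting step is the argmin of `k` at the queried
voltage (ties within 1e−9 relative are reported as a set; missing estimates
flag the result partial). Its fitted `d` against a threshold of 0.025
(configurable) classifies the pore: `d ≥ 0.025` energy-like, `d < 0.025`
entropy-like. The boundary value classifies as energy-like by the `≥`
convention.

**Diffusion limit.** Given an ion approach rate `n_appr`, the ceiling
current is `e·n_appr`; the per-point efficiency `i / e·n_appr` ≪ 1 marks
transport that is not diffusion-limited.

**Fluctuating voltage.** When the voltage drifts during a recording, each
interval between consecutive permeation events yields one observation:
current `e/Δt` and voltage the time average of the (linearly interpolated)
trace over the interval — an average rather than the instantaneous value at
the event, since the whole interval produced the event. Observations are
grouped into five equal-width voltage bins over the observed range by
default (explicit edges accepted; the binning of the original analysis is
not specified, so this is a package choice), and per-bin means reported
together with overall mean current and voltage. On a constant-voltage
record this reduces exactly to the event-count current.

## Numerical and design notes

- Generator rows sum to zero by construction; stationary probabilities are
  clipped of sub-tolerance negatives and renormalized.
- The shape classifier requires ≥ 3 strictly increasing positive voltages.
- Trajectory segment bookkeeping is validated to 1e−9 ns (tiling, ordering).
- File formats are plain text: cycle JSON (schema-validated with field
  paths), trajectory TSV + events TSV + JSON header, rate/fit/i-V CSV at
  full float precision. Every CLI run writes a manifest (config echo, seed,
  file list, version) sufficient to reproduce outputs bit-for-bit.
- Problem sizes in the tests and the acceptance script follow the reference
  ensemble design (100 × 10 ns × 5 voltages per cycle, ~0.5–1 s per cycle);
  convergence-style tests use 1 μs totals, where ensemble occupancy is
  within 0.02 total variation of the stationary law and the event rate
  within 5% of the model flux.

## Known limitations

- The four-state single-cycle topology is fixed per analysis; no hidden
  states, no dwell-time mixtures, no Bayesian uncertainty on rates.
- Backward rates are user-supplied only; nothing constrains them to satisfy
  detailed balance unless the user chooses them so.
- The event-derived i-V curve of a forward-only cycle reflects that model's
  nonzero zero-voltage flux (see above); absolute currents of a real pore
  are not reproduced by the forward-only idealization.
- Classification thresholds (bottleneck `d` cut 0.025, linearity tolerance
  5%) are interpretable conventions, not fitted quantities.
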