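# poreflux

Discrete-state kinetic analysis of single-file ion permeation through
nanopores — why some pores show saturating (sublinear) current-voltage
curves and others accelerating (superlinear) ones.

## The model

Ion transport through a narrow pore is represented as a cycle of
ion-occupancy states, e.g.

    S2 -> S2+1 -> S3 -> S1+2 -> S2

(two ions inside; a third arrives at the entrance; it enters; one leaves).
One traversal of the cycle transports net one ion. Each transition rate
depends exponentially on the applied transmembrane voltage *V*:

    k_ij(V) = k_ij(0) · exp(d_ij · e·V / k_B·T)

where *k_ij(0)* is the zero-voltage rate (ns⁻¹) and *d_ij* the *electrical
distance* — the fraction of the applied field sensed by the motion behind
the step. At 300 K the thermal voltage k_B·T/e is 25.852 mV, and a flux of
one ion/ns corresponds to 160.218 pA.

The shape of the i-V curve follows from the *d* of the slowest (rate-
limiting) step:

- **entropy-like bottleneck** (*d* ≈ 0 or negative): the step is blind to
  the field — e.g. the narrow phase space for swapping an entrance water
  with an incoming ion — and the current saturates: **sublinear** i-V.
- **energy-like bottleneck** (*d* ≥ 0.025): the field lowers the barrier —
  e.g. ion-ion repulsion during knock-on — and the current accelerates:
  **superlinear** i-V.

The package provides, for any user-defined cycle (two reference
parameterizations, `ANT-5` and `ANT-6`, ship with it):

- exact (Gillespie) stochastic simulation of state trajectories, seeded and
  reproducible, at the reference ensemble design of 100 × 10 ns per voltage;
- rate estimation by transition counting, `k_ij = N_ij / T_i` (equivalently
  `J_ij / P_i`), with Poisson errors;
- least-squares fitting of `ln k` vs `V` to recover `(k0, d)` per transition;
- steady-state solution and model i-V prediction for the cycle;
- i-V shape classification (linear / sublinear / superlinear), rate-limiting
  step identification, bottleneck classification, diffusion-limit comparison,
  and i-V reconstruction from permeation events under a fluctuating voltage.

## Worked example

```sh
$ cat ant5_config.json
{"cycle": "ANT-5", "n_trajectories": 100, "duration_ns": 10.0, "seed": 1}
$ poreflux analyze --config ant5_config.json --out-dir ant5_out
poreflux 0.1.0 analysis of cycle ANT-5
ensemble: 100 x 10 ns at 100/200/400/600/800 mV, seed 1

rate-limiting: S2->S2+1
  k0 = 8.768 ns^-1, d = -0.0821 (r^2 = 0.9999)
bottleneck: entropy-like (threshold d = 0.025)
i-V shape: sublinear (signed mean relative deviation +4.5849)
```

Five microseconds of synthetic trajectory data were simulated from the
`ANT-5` cycle (whose slowest step is parameterized `k0 = 8.5 ns⁻¹,
d = −0.079`), and the full count → estimate → fit chain recovered
`k0 = 8.768 ns⁻¹, d = −0.0821` for that step: the entry of an ion into the
doubly occupied pore. Its negative electrical distance means voltage cannot
accelerate it, so the pore is classified entropy-bottlenecked and its
event-derived i-V curve is sublinear. Running the same chain on `ANT-6`
identifies `S3+1->S2+2` (`k0 ≈ 6.1 ns⁻¹, d ≈ +0.100`) as rate-limiting —
an energy-like, voltage-accelerated bottleneck.

The same chain is available in Python:

```python
import poreflux as pf

result = pf.run_pipeline(pf.builtin_cycle("ANT-6"), seed=1)
print(result.limiting.transitions)   # (('S3+1', 'S2+2'),)
print(result.bottleneck)             # energy-like
print(result.fit.fits[("S3+1", "S2+2")].d)  # 0.0995
```

Per-stage subcommands (`simulate`, `estimate`, `fit`, `model-iv`,
`classify`) expose the pipeline step by step on TSV/CSV files; every run
writes a manifest with the seed and configuration for bit-for-bit
reproduction.

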