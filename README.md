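# camkinet

Rule-based kinetic modeling of the Ca²⁺ → calmodulin → CaMKII signaling
cascade in the postsynaptic density, with the scaffold neurogranin (Ng)
and the phosphatase PP1.

## The scientific problem

Dendritic spines convert brief calcium transients into long-lasting
biochemical state through CaMKII autophosphorylation at T286. Whether a
calcium spike phosphorylates CaMKII depends on a competition: calcium
activates calmodulin (CaM), but neurogranin sequesters calcium-free CaM
(the two bindings are mutually exclusive), limiting how much CaM is
available when a spike arrives. On top of this, the dodecameric CaMKII
holoenzyme only permits phosphorylation of a subunit by its dedicated
ring neighbor, and PP1 continuously reverses phosphorylation.

`camkinet` is for computational neuroscientists and systems biologists who
want to simulate this network quantitatively. It provides:

* a **deterministic monomer model** — the reaction rule set expanded by
  rule closure into a full mass-action network (214 species) and
  integrated with a stiff solver; used for equilibria, CaM dose–response
  scans and calibration;
* a **network-free stochastic holoenzyme model** — 63 discrete
  dodecamers (two rigid hexameric rings each; kinase at ring position *i*
  targets position *i+1*), individual CaM/Ng/PP1 molecules and calcium
  ions in the 0.0156 μm³ PSD volume, simulated with an exact Gillespie
  algorithm (time-inhomogeneous calcium influx handled by thinning);
* **calcium input protocols** (clamps, calibrated ~10 μM single spikes,
  0.5 Hz trains) and the **response analysis**: ΔAUC/Δpeak/lifetime
  metrics, responder statistics, 10:1 pulse ratios and the
  leaky-integrator fit

  x(t) = k·(1 − e^(−a·t)),

  whose capacity *k* (μM) and rate *a* (s⁻¹) quantify how CaMKII
  integrates — and leaks — calcium signals, and how Ng tunes both.

All kinetic constants ship in a plain-text rate table
(`src/camkinet/data/rate_table.tsv`); every output bundle embeds its full
configuration, protocol and seeds for bit-identical reproduction.

## Worked example

Equilibrium Ng sequestration, then a stochastic 30-pulse train with the
leaky-integrator fit:

```python
import numpy as np
from camkinet import (build_rule_set, generate_network, load_rate_table,
                      equilibrate, calibrate_pulse, make_pulse_train,
                      run_ensemble, delta_curve, ensemble_average,
                      fit_leaky_integrator)
from camkinet import species as sp

rates = load_rate_table()
net = generate_network(build_rule_set(True),
                       [sp.CA, sp.cam(0, 0), sp.NG, sp.k("U"), sp.PP1],
                       rates)

# 30 uM CaM + 20 uM Ng at 100 nM free calcium: how much CaM is sequestered?
ss = equilibrate(net, {"CaM": 30.0, "Ng": 20.0}, target_free_ca=0.1)
print(round(ss.concentration(sp.CAMNG), 2))      # -> 19.62  (uM CaM.Ng)

# calibrate a ~10 uM free-calcium spike in the full buffering context,
# then run 12 stochastic holoenzyme trains (30 pulses at 0.5 Hz, no Ng)
steady = equilibrate(net, {"CaM": 30.0, "Ng": 0.0, "K": 80.0, "PP1": 1.25},
                     target_free_ca=0.1)
cal = calibrate_pulse(net, steady, target_peak=10.0)
proto = make_pulse_train(30, 0.5, amplitude=cal.amplitude, k_e=cal.k_e,
                         start=5.0)
runs = run_ensemble(rates, proto, n_runs=12, base_seed=1, cam_total=30.0,
                    ng_total=0.0, t_end=proto.onsets[-1] + 10.0)
curves = [delta_curve(r.t, r.conc("n_p"), (0.0, 4.75), 5.0) for r in runs]
mean = ensemble_average(curves, [r.meta["n_phospho_events"] > 0
                                 for r in runs], "all").mean
fit = fit_leaky_integrator(mean, window=(0.0, 65.0))
print(round(fit.k, 2), round(fit.a, 3), round(fit.r_squared, 3))
# -> 5.11 0.038 0.978   (capacity uM, rate 1/s, R^2; stochastic, seed 1)
```

The first number says ~19.6 of the 30 μM CaM is Ng-bound at rest — the
spike must out-compete Ng for the remainder. The fit says that without Ng
the holoenzyme population integrates the train toward a plateau of a few
μM phosphorylated subunits with a leak set by PP1; repeating with
`ng_total=20.0` collapses the capacity by over an order of magnitude
(k ≈ 0.4 μM) while the rate roughly doubles — Ng retunes both parameters
of the integrator.

The same analyses are scripted as named experiments:

```sh
camkinet simulate train-30 --set ng=0 --set n_runs=12 --out runs/
camkinet reproduce bistability-check
```

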