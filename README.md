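# condx

Quantitative tools for measuring and modeling **molecular exchange in
biomolecular condensates** with flow cytometry.

Proteins in liquid-like condensates (e.g. nucleophosmin/NPM1 droplets formed
by liquid–liquid phase separation) continuously exchange with the
surrounding solution. As condensates age, their interface solidifies and
exchange slows — a hallmark of maturation that two-color flow cytometry can
read out at scale: pre-formed red-labeled condensates are mixed with
blue-labeled protein, and the fraction of double-positive (red⁺/blue⁺)
events tracks exchange over time. This package provides the modeling and
analysis layer for that assay, for biophysicists and cytometrists working on
phase-separated systems.

## The model

Exchange of a single protein into a preformed condensate is a three-state
continuous-time Markov chain

```
dilute  --k_on-->  interface  --k_entry-->  dense (absorbing)
dilute  <--k_bounce--  interface
```

where `k_bounce` is the interface resistance, which grows with condensate
age. With S = k_on + k_bounce + k_entry, Δ = √(S² − 4·k_on·k_entry), and
α± = (S ± Δ)/2, the first-passage time into the dense phase has density

    F(t) = (k_on·k_entry/Δ) · (e^(−α₋t) − e^(−α₊t)),

closed-form CDF, Laplace transform F̃(s) = k_on·k_entry / (s(s+S) +
k_on·k_entry), and mean first-passage time (MFPT)

    T_exchange = (k_on + k_bounce + k_entry) / (k_on · k_entry).

Aging presets (`early`, `intermediate`, `late`) hold k_on = 0.05 s⁻¹ and
k_entry = 0.1 s⁻¹ while k_bounce takes 0.01, 0.1, 1.0 s⁻¹ — MFPT 32 s,
50 s, 230 s.

The package also includes:

- an exact Gillespie simulator of the chain (independent stochastic oracle),
- a synthetic two-color assay generator (lognormal droplet sizes, interface
  heterogeneity, 10–15 s acquisition dead time, detection thresholds,
  measurement noise, optional immobile fraction),
- cytometry analytics: FCS/CSV event I/O, ungated MFI, quadrant analysis,
  double-positive time courses, aspect-ratio/area gating for imaging flow
  cytometry, Student's t-test,
- maximum-likelihood inference of exchange rates from double-positive counts
  (binomial likelihood, multi-start bounded optimization, profile-likelihood
  intervals),
- sequence charge analytics: net domain charge and Sequence Charge
  Decoration (SCD) for charge-patterned proteins such as NPM1.

## Worked example

Simulate an exchange assay for intermediate-age condensates (true
k_bounce = 0.1 s⁻¹, MFPT 50 s), analyze it, and re-infer the rate:

```python
import numpy as np, condx

rates = condx.aging_preset("intermediate").rates
config = condx.ExchangeAssayConfig(rates=rates,
                                   timepoints=tuple(np.linspace(0, 250, 12)))
result = condx.generate_exchange_assay(config, seed=7)
course = condx.double_positive_timecourse(result.tables,
                                          condx.default_gates(config))
print(course[["time_s", "n_dp", "dp_fraction"]].head(5).to_string(index=False))
tc = condx.Timecourse.from_dataframe(course)
fit = condx.fit_exchange(tc, free=("k_bounce", "dead_offset"), seed=0)
print(fit.estimates)
print(condx.profile_interval(fit, tc, "k_bounce")[:2])
```

prints

```
   time_s  n_dp  dp_fraction
 0.000000    54       0.0054
22.727273  5115       0.5115
45.454545  7936       0.7936
68.181818  8926       0.8926
90.909091  9259       0.9259
{'k_bounce': 0.1005, 'dead_offset': 5.2933}
(0.0984, 0.1027)
```

Each of the 12 timepoints holds 10,000 droplet events; the double-positive
fraction climbs from 0.5% to ~93% over 91 s as blue protein crosses each
droplet's interface. The fitted interface-resistance rate (0.1005 s⁻¹, 95%
profile interval 0.098–0.103) recovers the generating value 0.1 s⁻¹; the
fitted offset absorbs the lag between mixing and the first detectable
threshold crossing.

The same workflow is available from the shell:

```bash
condx kinetics --preset early --mfpt          # prints 32 (seconds)
condx sample --preset late -n 100000 --seed 42 --out times.csv
condx simulate-assay assay.json --seed 7 --out-dir events/
condx analyze quadrant --red-thr 500 --blue-thr 500 events/events_*.csv --out dp.csv
condx fit --timecourse dp.csv --free k_bounce,dead_offset --out fit.json
condx seqcharge --fasta npm1.fasta --range 119:242 --stat scd,net
```

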