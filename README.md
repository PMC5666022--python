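# antdrip

Agent-based model of **ant droplet formation**: when an aggregation of ants
hangs from a support and grows into chains and bridges, groups of ants
("droplets") periodically detach and fall.  Experimental work has shown
that the time series of these droplets resembles a chaotic dripping faucet
— heavy-tailed interdrop statistics emerging from a living system.
`antdrip` implements a lattice model in which that behaviour arises from
individual decision rules: each embedded ant carries a *weight threshold*
and adaptively re-tunes it from local pattern cues and propagated warning
signals.  The package bundles the simulator with the time-series analysis
used to characterise its output (interdrop intervals, fluctuation scaling,
Lévy vs. exponential model selection).

It is aimed at researchers in collective animal behaviour and
self-organisation who want a reproducible, scriptable implementation of
the model and its statistics.

## Model

Agents enter a 2-D lattice at rate Φ from a one-site rod and perform a
biased walk (−y with probability 0.9, ±x with 0.05 each by default) until
they reach an empty site strictly below the rod row, where they attach and
become *inactive*.  Each inactive agent k bears the weight of the agents in
its *supporting area* — the three-column region strictly below it; a site's
occupants hang from the topmost inactive agents whose area covers it, split
equally within that row (a single supporter carries its whole set).  The
per-step cycle is:

1. **Move down** (active agents, synchronous).
2. **Weight calculation** (after removal of laterally unsupported agents).
3. **Warning signal**: if `weight_k ≥ threshold_k − 1`, active agents
   directly below k climb one site onto the structure.
4. **Threshold coordination** (TM variants only): an inactive agent next to
   a climbing agent re-tunes its threshold using last step's pattern
   estimate — perceived-unstable: `threshold_k ← weight_k`;
   perceived-stable: `threshold_k ← threshold_k + 1`.
5. **Local pattern calculation**: stable iff a lateral inactive neighbour
   exists on the same row.
6. **Fall**: every k with `threshold_k ≤ weight_k` sheds the agents in its
   supporting area as one droplet; k survives with weight 0.

Four variants differ only in step 4: **TM** (both rules), **NTM** (none),
**TM-stable** (raise only), **TM-unstable** (collapse only).

The statistics layer computes interdrop intervals `DT(n)`, increments
`I(n) = DT(n+1) − DT(n)`, the fluctuation function
`F(n) = √⟨(Y(k+n) − Y(k))²⟩` of the mean-subtracted cumulative profile
`Y` (with scaling exponent α), and closed-form MLE fits of nonzero `|I|`
to a Pareto tail (`μ̂ = 1 + n/Σ ln(x/x_min)`) and a shifted exponential
(`λ̂ = 1/mean(x − x_min)`), compared by Akaike weights and a log-binned
G-test.

## Worked example

Run the standard threshold-modified experiment (5 trials, 1000 steps,
default parameters) and fit the increment tail:

```bash
antdrip batch --preset tm_fits --seed 1 --out-dir out
```

prints (abridged):

```json
{
  "variant": "TM",
  "n_trials": 5,
  "droplets_per_trial": 43.2,
  "mean_droplet_size": 21.19,
  "n_increments": 127,
  "mu": 1.611,
  "aic_weight_power_law": 1.0,
  "preferred_model": "power_law",
  "mean_max_width": 5.0,
  "mean_max_height": 26.2
}
```

Read: the model drips ~43 droplets per 1000-step trial; the 127 pooled
nonzero increment magnitudes are decisively power-law distributed (Akaike
weight 1.0) with exponent μ ≈ 1.61 — the Lévy signature of the adaptive
threshold rule — and the hanging structure is tall and narrow (mean
maximal extent 5 wide × 26 deep).  Replacing `tm_fits` with `ntm_fits`
switches off threshold coordination; `threshold3`, `threshold7`,
`broad_movement` and `multi_height` reproduce the remaining parameter
studies.  The same pipeline is available as a library
(`antdrip.run_trials`, `antdrip.compare_tail_models`, ...), and
`antdrip analyze series.csv` fits an externally supplied interval series.

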