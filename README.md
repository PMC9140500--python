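# polyinfer

Polymerizing biochemical circuits for real-time approximate Bayesian
inference in two-state Markov environments.

A reactor is driven by a discrete-time Markov chain over two states, A
and B: at fixed intervals the sampled state's species is pulsed in
(after removing any prior free A/B on a state change). A rule-based
circuit assembles linear *transition history polymers* from T-monomer
seeds; every tail extension emits one memory molecule encoding the
(previous terminal → added monomer) pair. Transition-encoding memory
(A-To-B, B-To-A) and duration-encoding memory (A-To-A, B-To-B) compete
for fixed pools of integrators, bound mutually exclusively, so the
activator-bound integrator fraction realizes a molecular
normalization-sampling of the transition counts — an approximate
posterior over the chain's switch probabilities. The package also
contains the exact conjugate-Bayes baseline this approximates, the
comparison analyses between the two, and an anticipatory gene-program
(B-Program) regulation circuit whose rate constants are calibrated
against a sawtooth target by derivative-free optimization.

## Modules

- `polyinfer.environment` — Markov environment sampling, perturbation
  schedules, piecewise (regime-switching) schedules.
- `polyinfer.inference` — transition-count sufficient statistics, Beta
  posteriors under a uniform prior, posterior medians, predictive
  distribution, reference normalization-sampling, posterior timecourses.
- `polyinfer.circuit` — monomers/polymers, memory species, integrator
  pools, rate constants, and the full mass-action rule set.
- `polyinfer.simulator` — exact stochastic simulation (Gillespie direct
  method) interleaved with the timed perturbation schedule; polymer
  sequences reconstructed by replaying recorded firings.
- `polyinfer.analysis` — circuit-vs-baseline ratio sweep with pooled
  Spearman rank correlation; qualitative tracking metrics.
- `polyinfer.calibration` — B-Program regulation rules, sawtooth target
  profiles, Nelder–Mead rate calibration in log-rate space with common
  random numbers.
- `polyinfer.cli` / `polyinfer.config` / `polyinfer.presets` — unified
  CLI, YAML configuration with resolved-config dumps, figure presets.

## CLI

```sh
polyinfer env-gen  --config cfg.yaml --seed 1 --out out/env
polyinfer simulate --config cfg.yaml --seed 1 --out out/run
polyinfer sweep    --replicates 20 --seed 1 --out out/sweep
polyinfer calibrate --budget 200 --seed 1 --out out/cal
polyinfer preset fig3 --seed 1 --out out/fig3   # fig3..fig7
```

Configuration is a YAML file with `environment`, `circuit`, `rates`,
`analysis` and `calibration` blocks (see `resolved_config.yaml` written
by any run for the full set of keys and defaults). Every run can be
reproduced byte-identically from its resolved config.

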