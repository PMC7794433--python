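# qscomm

Quantitative modelling of a **feedback-free peptide quorum-sensing
system** — the ComQXPA channel of *Bacillus subtilis*, in which the
signal peptide ComX does not stimulate its own production, yet the
population still switches sharply from basal to maximal gene expression.

The package is a library for systems biologists who want to fit, simulate
and stress-test the encoder–decoder decomposition of such a channel:

* **Encoder** (density → signal): the allometric law *SM(N) = a·Nᵇ*.
  With *b ≈ 2* the signal rises with the *square* of cell density — an
  ultra-sensitive encoder. The same law follows from per-cell production
  proportional to μ(t)·N(t) (specific growth rate × density):
  d*SM*/dt = c·μ·N² integrates to (c/2)(N² − N₀²).
* **Decoder** (signal → response): the Hill law
  *W(SM) = W*max *SMⁿ/(Kmⁿ + SMⁿ)*; *n > 1* marks cooperative,
  ultra-sensitive activation.
* **Growth-coupled response dynamics**:
  *RM(t)/N(t) = RM₀/N(t) + RM₁(t)/N(t)* with
  d*RM₁*/dt = *k·Ŵ(SM(t))·μ(t)·N(t)* — overnight reporter stock diluting
  by division plus signal-driven synthesis, producing the characteristic
  dip-then-upturn per-cell trajectory.
* **Switch sharpness**: composing the two stages gives the response as a
  function of density alone; *n*gen = log₂(*N*₀.₇₅/*N*₀.₂₅) =
  log₂ 9/(b·n) counts the doublings needed to traverse the central
  response window. Only dual ultra-sensitivity (*b* > 1 **and** *n* > 1)
  completes the switch within a single generation.

Around this core sit the measurement-side analyses: biosensor-based
absolute quantification from paired calibration/sample sigmoids with a
blank + 3 SD limit of detection, the lower-limit-of-response rule,
growth-rate and competition fitness comparisons, OD–dissolved-oxygen
correlation, single-cell lognormal deconvolution / Grubbs hyperproducer
detection / co-localization against a simulated null, modified-Z
microplate QC, and an ATP ledger for the cost of one signal peptide.
Seeded generators emulate every dataset, so each fitting stage has a
statistical inverse to test against.

## Worked example

```python
import qscomm as q

cfg = q.SimConfig(seed=1)                      # operating point: a=9.6, b=2.09,
series = q.gen_sm_series(cfg)                  #   Km=4 nM, n=2.3, k=760, RM0=5.5
enc = q.fit_allometric(series)
traj = q.gen_response_trajectory(cfg)
dyn = q.fit_dynamics(traj, cfg.growth, enc, cfg.decoder)
print(enc.a, enc.b, dyn.k, dyn.rm0)
print(q.n_gen(q.ModeSpec(enc, cfg.decoder)).n_gen)
```

Running the shipped scripts prints, for example:

```text
$ python examples/encoder_fit.py
a = 9.51 +- 0.07 nM (a.u.)^-b   [truth 9.6]
b = 2.099 +- 0.008               [truth 2.09]
```

(the signal at OD650 = 1 sits near 10 nM and grows with the square of
density),

```text
$ python examples/switch_sharpness.py
encoder=ultra  decoder=ultra   n_gen = 0.66 ...
encoder=linear decoder=ultra   n_gen = 1.38 ...
encoder=ultra  decoder=linear  n_gen = 1.52 ...
encoder=linear decoder=linear  n_gen = 3.17 ...
```

(half of the response arrives within ~0.7 of a generation only when both
stages are ultra-sensitive), and

```text
$ python examples/peptide_atp_cost.py
total : 484.0 ATP per molecule
```

(one signal peptide costs 484 ATP — vastly more than an acyl-homoserine
lactone, offset by the nanomolar working range). Each script in
`examples/` builds a small synthetic input, runs one capability and
explains its numbers; a thin `qscomm` CLI exposes the same operations on
CSV files (`qscomm fit-encoder data.csv`, `qscomm modes`,
`qscomm reproduce --seed 1`).

## Layout

```
src/qscomm/        encoder, decoder, growth, dynamics, modes, biosensor,
                   single_cell, peptide_cost, synthetic, pipeline, io, cli
examples/          one narrative script per capability
tests/             unit + property + end-to-end recovery suites
docs/methods.md    modelling assumptions, defaults, numerical choices
```
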