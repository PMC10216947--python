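# edukin

Cell-cycle kinetics from thymidine-analog (EdU) labeling experiments.

`edukin` is a toolkit for quantitative proliferation studies of the kind
used to characterize regenerating tissue — e.g. the posterior blastema of
the annelid *Alitta virens* — where confocal stacks of EdU/DAPI-stained
specimens are counted, labeling indices are tracked over time, and
cell-cycle parameters are extracted from cumulative-labeling curves.  It
provides:

* **kinetics** — the closed-form cumulative/pulse labeling model.  Under
  continuous exposure the labeling index rises as
  `LI(t) = GF·(t + Ts)/Tc` and plateaus at the growth fraction `GF` once
  `t ≥ Tc − Ts`; the rising line `y = a + b·t` encodes the parameters as
  `Ts = a/b`, `Tc = GF/b = breakpoint + Ts`.
* **fitting** — broken-line-with-plateau least squares recovering
  (GF, Ts, Tc) from LI data, with an exact breakpoint-interval scan,
  earliest-consistent-breakpoint selection, non-identifiability flagging
  and case-resampling bootstrap intervals.
* **simulate** — an agent-based generator of pulse, cumulative and
  pulse-wait (pulse-chase) experiments with label dilution at division,
  exact event-driven dynamics, and per-specimen random substreams.
* **stats** — mean ± SEM summaries, Kruskal–Wallis and pairwise
  Mann–Whitney tests, exact by full enumeration for small samples.
* **imaging** — synthetic two-channel confocal stacks with ground truth,
  and diameter-parameterized nuclei counting (DoG band-pass + local
  maxima), replacing interactive spot counting with a reproducible step.

## Worked example

Two published mean LI series from cumulative EdU exposure of regenerating
worms ship with the package.  Fitting the series that starts at 2 days
post-amputation:

```python
>>> from edukin import fit_cumulative
>>> from edukin.datasets import load_cumulative_series
>>> s = load_cumulative_series("2dpa")   # times 0.25, 10, 24, 48 h
>>> fit = fit_cumulative(s.time_h, s.li_percent)
>>> print(f"GF = {fit.gf:.1f} %   Ts = {fit.ts:.2f} h   "
...       f"Tc = {fit.tc:.2f} h   breakpoint = {fit.breakpoint:.2f} h")
GF = 76.0 %   Ts = 7.33 h   Tc = 25.82 h   breakpoint = 18.49 h
```

Interpretation: 76% of cells in the bud are actively cycling, the S-phase
lasts about 7.3 h, and a full cycle about 25.8 h; the curve stops rising at
`Tc − Ts ≈ 18.5` h, when every cycling cell has passed through S at least
once.  The same call on the 1 dpa series gives `GF = 85.7 %` with a much
shorter S-phase (≈ 1 h against the published ≈ 1.3 h estimated from richer
per-specimen data).

The simulator closes the loop — generate a synthetic experiment under
known kinetics, then recover the parameters:

```python
>>> from edukin import CellCycleParams, LabelingProtocol, simulate_experiment
>>> p = CellCycleParams(tc=25.7, ts=7.3, gf=76.0)
>>> proto = LabelingProtocol.cumulative([0.25, 5, 10, 24, 48])
>>> df = simulate_experiment(p, proto, n_cells=2000, n_specimens=6, seed=1)
>>> refit = fit_cumulative(df.time_h, df.li_percent)
>>> print(f"GF = {refit.gf:.1f} %   Ts = {refit.ts:.2f} h   Tc = {refit.tc:.2f} h")
GF = 76.0 %   Ts = 7.43 h   Tc = 26.21 h
```

The same pipeline is available from the shell:

```sh
edukin simulate --preset cumulative-2dpa --seed 1 --out run/
edukin fit run/counts.csv --n-boot 500 --out run/
edukin stats run/counts.csv --out run/
edukin imagesim --n-nuclei 300 --labeled-fraction 0.25 --seed 1 --out img/
edukin count img/stack.tiff --out img/
```

Every command writes its resolved configuration and a log next to its
outputs, so runs are reproducible bit-for-bit from the recorded config.

See `docs/methods.md` for the model's assumptions, the breakpoint
selection rule, what the synthetic generators do and do not emulate, and
known limitations.

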