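# gelcell

Diffusion-cell transport analysis for pharmaceuticals in hydrogels.

Soil organic matter binds trace pharmaceuticals and slows their spread. A
clean laboratory model of that situation is a two-compartment diffusion
cell: a thin agarose hydrogel slab — optionally enriched with humic acids
as a stand-in for soil organic matter — separates a stirred *donor*
reservoir loaded with drug from a stirred *acceptor* reservoir of water,
and the concentration in both reservoirs is followed over time. `gelcell`
provides, as one tested pipeline:

- a **forward simulator** of the cell: 1-D Fickian diffusion through the
  slab with instantaneous linear binding (retardation) and an interface
  partition coefficient, coupled to finite well-mixed reservoirs, plus a
  Langmuir batch adsorption/desorption generator — so that fully synthetic
  experiments with known ground truth can be produced;
- the **estimation chain** a bench scientist applies to such traces: lag
  time, lag-stage diffusivity, per-record flux and effective diffusivity,
  apparent binding constant, and mass-balance partition coefficient;
- **batch sorption statistics**: adsorption efficiency and the
  mobile/strongly-bound split of the desorption step.

## The model

Free drug at concentration $u(x,t)$ diffuses through a slab of thickness
$L$ and area $A$; binding sites immobilise $c_b = K u$ instantaneously, so

$$(1+K)\,\partial_t u = D\,\partial_x^2 u, \qquad
u(0,t)=\varepsilon\,c_d(t),\quad u(L,t)=\varepsilon\,c_a(t),$$

with the reservoirs evolving from the face fluxes,
$V_d\,\dot c_d = +AD\,\partial_x u|_0$ and
$V_a\,\dot c_a = -AD\,\partial_x u|_L$. $K$ is the apparent binding
equilibrium constant (0 for plain agarose), $\varepsilon$ the gel/solution
partition coefficient.

The estimators invert this model the classical way:

- **time lag**: the quasi-steady cumulative permeation line
  $Q(t)=V_a c_a(t)$ intercepts the time axis at
  $t_\mathrm{L} = L^2(1+K)/(6D)$, so $D_\mathrm{L} = L^2/(6 t_\mathrm{L})$;
- **flux**: per record, $j = -V_d\,\Delta c_d/(A\,\Delta t)$ and
  $D_\mathrm{E} = -jL/\Delta c$ with $\Delta c = c_a - c_d$;
- **binding**: comparing inert and humic-enriched gels,
  $K = D_\mathrm{inert}/D_\mathrm{reactive} - 1$;
- **partition**: the closed-cell mass balance gives the mean gel
  concentration, $\hat\varepsilon = c_h\,/\,\tfrac12(c_d+c_a)$ (for a
  reactive gel this reads $\varepsilon(1+K)$, since bound drug cannot be
  separated from free drug by mass balance).

## Worked example

Simulate the sulphapyridine scenario — a 5 mm × 40 mm slab between 50 cm³
reservoirs, 25 mg/dm³ donor solution, inert gel versus a humic-enriched gel
with $K=1.92$, 1% measurement noise — and run the full estimation chain:

```sh
gelcell pipeline -c examples/sulphapyridine.toml --seed 1 --outdir demo
```

`demo/results.csv` (seed 1):

```
  sample  t_L_min  D_L_e10  D_E_e10  K_first  K_second  epsilon
   inert  128.632    5.399    4.850      NaN       NaN    1.052
reactive  369.230    1.881    5.831     1.87    -0.168    2.733
```

Reading the table: the lag time stretches from ~129 min (true value
133.5 min) to ~369 min (true 390 min) when humic acids are present, the
lag-stage diffusivity drops accordingly (units of $10^{-10}$ m²/s), and
their ratio recovers the binding constant, $\hat K = 1.87$ against the
generating value 1.92. In the second stage both gels show the same
effective diffusivity ($K_\text{second}\approx 0$) because transport then
happens through an already-equilibrated gel. The apparent partition
coefficient of the reactive gel, 2.73, approaches $\varepsilon(1+K)=2.92$:
the mass balance counts the bound drug as gel content. A `run.log` records
the config hash, seed and every estimator decision; re-running with the
same seed reproduces all artifacts byte for byte.

The same operations are available as a library
(`simulate_cell`, `estimate_lag_time`, `d_from_lag`, `flux_series`,
`apparent_equilibrium_constant`, `partition_coefficient`,
`simulate_sorption`, `sorption_table`, …), and `gelcell sorption
--simulate` produces the batch adsorption/desorption summary table.

## Layout

- `src/gelcell/simulate.py` — cell geometry/transport types, the implicit
  slab/reservoir solver, noise model, Langmuir batch generator
- `src/gelcell/estimate.py` — lag, flux, binding and partition estimators
- `src/gelcell/sorption.py` — batch sorption percentages and tables
- `src/gelcell/io.py`, `config.py`, `pipeline.py`, `cli.py` — CSV/TOML
  formats, calibration, the reproducible pipeline and the CLI
- `docs/methods.md` — modelling assumptions, numerical choices, estimator
  accuracy and limitations
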