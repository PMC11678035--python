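# Methods

## Physical model

The cell is modelled as a 1-D slab (thickness $L$, exposed area $A$)
between two well-mixed reservoirs. Three mechanisms are represented:

1. **Fickian diffusion** of the free drug in the gel, diffusivity $D$
   (m²/s).
2. **Instantaneous linear binding**: humic binding sites hold
   $c_b = K\,u$ in local equilibrium with the free concentration $u$.
   Because binding is linear and fast relative to diffusion, it enters the
   transient only as the retardation factor $1+K$:
   $(1+K)\,\partial_t u = D\,\partial_x^2 u$. The steady flux is
   unaffected; the lag time is stretched to $L^2(1+K)/6D$. No kinetic or
   nonlinear (Langmuir) in-gel binding is modelled.
3. **Interface partitioning**: at both faces the free gel concentration is
   slaved to the adjacent reservoir, $u = \varepsilon\,c$, with one
   $\varepsilon$ for both faces. For a ~99% water agarose gel
   $\varepsilon \approx 1$.

Reservoirs change only through the face fluxes; the total drug mass
(donor + acceptor + free and bound gel content) is conserved exactly in
the continuum model, and to rounding error (~1e-10 relative) in the
discretisation — conservation is an invariant of the scheme, not an
accuracy target.

Units: concentrations are carried in g/m³, numerically identical to the
bench unit mg/dm³, so no conversion factors appear anywhere; lengths and
times are SI. User-facing tables report lag in minutes and diffusivities
in $10^{-10}$ m²/s, the conventional scales for hydrogel work.

### Defaults (the emulated bench experiment)

| parameter | default | why |
|---|---|---|
| slab | 5 mm thick, 40 mm diameter | the cast hydrogel disc geometry |
| reservoirs | 50 cm³ each | typical side-by-side bench cell; measured donor depletion is appreciable but not dominant, consistent with the depletion visible in such experiments; always configurable |
| $c_0$ | 25 mg/dm³ (sulphapyridine-like), 2.5 (diclofenac-like) | the bench initial concentrations; the lower one reflects diclofenac's poor solubility |
| $D$ | 5.20e-10 m²/s inert / configurable | inert-gel sulphapyridine diffusivity scale |
| $K$ | 0 inert, 1.92 reactive default | first-stage binding constant of the humic gel |
| noise | sd = 1% of reading + 0.02 mg/dm³ | UV/VIS read noise scale; Gaussian, clipped at zero, seed mandatory |

## Numerics

Vertex-centred uniform grid (default 101 nodes), backward-Euler time
stepping (unconditionally stable for the stiff reservoir coupling),
default internal step $L^2(1+K)/D/2000$, subdividing the output interval
evenly. Face nodes are eliminated via the partition relation; ordering the
unknowns $[c_d, u_1, \dots, u_{n-2}, c_a]$ makes the implicit system
tridiagonal (solved with `scipy.linalg.solve_banded`). The reservoir
balance uses the first-order face difference with the half-node gel mass
folded into an effective reservoir capacity; written this way the scheme
conserves the discrete total mass (trapezoidal gel content plus
reservoirs) identically for any step size, which a naive Dirichlet
coupling does not. Negative concentrations beyond 1e-9 of the scale abort
with a solver error naming the offending setting.

Accuracy, measured against the closed-form permeation series for a
constant-donor/sink cell: cumulative permeated amount within 1% after the
transient; doubling both resolutions moves every sample by under 0.1% of
the concentration scale (relative convergence of the very small
near-breakthrough acceptor values is intrinsically harder — they sit on
the exponentially steep front — which is why convergence is stated against
the scale, i.e. the measurement resolution, not pointwise).

## Estimators

**Lag time (default: extrapolation).** The classical construction fits a
line to the quasi-steady part of $Q(t) = V_a c_a(t)$ and takes the
positive time-axis intercept. Two choices matter:

- *Window selection.* The fit uses the contiguous run of records whose
  smoothed permeation rate (moving average over ~1/10 of the
  post-breakthrough span) is within 1% (`slope_tol`) of its maximum — the
  plateau where the flux has genuinely settled. Goodness-of-fit criteria
  such as an $R^2$ cut-off were evaluated and rejected: on smooth
  noiseless traces $R^2$ stays above 0.999 across strongly curved windows,
  which drags the intercept toward the transient (up to tens of percent of
  $t_L$ with finite reservoirs). If the plateau holds fewer than
  `min_points` (10) records — typical of noisy traces — the trailing 30%
  of post-breakthrough records is used instead.
- *Donor-depletion correction.* With finite reservoirs the driving force
  decays, curving $Q(t)$ and biasing the intercept. The fit is therefore
  performed against the driving-force-corrected abscissa
  $\theta(t) = \int_0^t (c_d - c_a)\,ds\,/\,(c_d(0)-c_a(0))$ and the
  intercept mapped back through $\theta$; for a near-constant donor
  $\theta = t$ and the construction is the textbook one.

Measured accuracy (noiseless): within ~1% of $L^2(1+K)/6D$ with
near-constant donor, −3% to −8% with 50 cm³ reservoirs (residual depletion
bias, worst for long runs); with 1% read noise on the bench cell, the
median of 25 replicates stays within ~3% and the replicate sd is the
reported lag uncertainty. The alternative `threshold` method simply
returns the first time the acceptor exceeds 3× the noise floor (estimated
from the pre-breakthrough baseline unless given).

**Flux / effective diffusivity.** Per consecutive record pair, flux from
donor depletion (`side="acceptor"` or `"both"` switch the bookkeeping),
$\Delta c$ at the pair midpoint, $D_E = -jL/\Delta c$. Records with
$|\Delta c|$ under 1% of $c_0$ are flagged and excluded: near equilibrium
the ratio degenerates. $D_E$ is reported as mean ± sd over the valid
second-stage records; early second-stage records still carry transient
flux, so runs should extend to several lag times (the residual transient
decays like $e^{-\pi^2 D t/L^2(1+K)}$).

**Binding constant.** $\hat K = D_\text{inert}/D_\text{reactive} - 1$,
computed per stage (lag-stage diffusivities give the first-stage $K$,
effective diffusivities the second-stage one). No uncertainty propagation
beyond the component sds is attempted, because how the original ± values
were defined is not stated.

**Partition coefficient.** From the closed-cell mass balance,
$m_h = V_d c_0 - V_d c_d - V_a c_a$, $c_h = m_h/V_\text{gel}$,
$\hat\varepsilon = c_h / \tfrac12(c_d + c_a)$, evaluated at the final
record or averaged over the trailing quarter of the second stage. The
estimator deliberately reports $\varepsilon(1+K)$ for reactive gels —
bound drug cannot be told apart from free drug by mass balance alone, and
the same attribution applies to the bench analysis. A gel amount more
negative than 2% of the load raises a data-quality error rather than
returning a silent negative.

All estimators are invariant under rescaling every concentration by a
constant, so an uncalibrated absorbance trace (via the linear calibration
helper) yields the same $t_L$, $D_L$, $D_E$, $K$ and $\varepsilon$.

## Batch sorption generator and statistics

The adsorption step solves the vial mass balance
$c_0 V = cV + m\,q_\text{max} K_L c/(1+K_L c)$ for the equilibrium
concentration (stable quadratic root). The desorption step re-equilibrates
only the mobile share $1-f_s$ of the sorbed amount with fresh water of the
same volume through the same isotherm; the strongly bound share $f_s$ is a
fixed parameter, optionally with a linear dose dependence
(`strong_fraction_slope`), not a second isotherm — the experiment reports
only a mobile/strong split. Defaults $q_\text{max} = 2$ mg/g,
$K_L = 0.1$ dm³/mg describe a moderate-affinity humic sorbent at the bench
ratio of 5 cm³ solution per 100 mg sorbent; dose series default to
1–10 mg/dm³ (sulphapyridine-like) and 0.5–2.5 mg/dm³ (diclofenac-like),
five levels each.

Two preset behaviours reproduce the qualitative contrast between the
drugs: with fixed $f_s$ (sulphapyridine-like), adsorption efficiency falls
with dose while the measured mobile fraction rises, because saturation
weakens re-adsorption during the water step; with a dose-increasing $f_s$
(diclofenac-like, $f_s = 0.35 + 0.15\,c_0$), both percentages fall. Note
the *measured* mobile fraction equals $1-f_s$ only when re-adsorption is
negligible ($m\,q_\text{max}K_L \ll V$); at the default affinity most of
the mobile pool re-adsorbs, as it would on a real strongly sorbing humic
sample.

## What the synthetic data does and does not emulate

Emulated: geometry and volumes of the cell, realistic diffusivity/binding
ranges, donor depletion, interface partitioning, heteroscedastic read
noise, Langmuir saturation and the mobile/strong desorption split.
Not emulated: concentration-dependent diffusivity, in-gel nonlinear
binding, sorption/desorption kinetics (all equilibria are instantaneous),
temperature drift, stirring imperfections (reservoirs are ideally mixed),
gel swelling or face asymmetry, and spectrometer artefacts beyond a linear
calibration. Passing tests therefore demonstrate correctness of the
analysis chain under the stated model, not the validity of that model for
any particular real gel.

## Problem sizes

Test and acceptance runs use traces of 400–1300 samples (6–10 lag times at
60–240 s sampling) on the 101-node grid; the recovery grid covers
$D \in \{1, 2.5, 5\}\times10^{-10}$ m²/s, $K \in \{0, 0.5, 2\}$,
$\varepsilon \in \{0.8, 1.0\}$ with near-constant-donor reservoirs
(2 dm³), where the lag construction is bias-free; noisy Monte-Carlo checks
use 25 replicates on the 50 cm³ bench cell, where the acceptor signal is
strong enough for the noise model to be the dominant error source.

## Known limitations

- The time-lag estimator retains a few-percent negative bias on finite
  cells driven hard into depletion; use larger reservoirs or shorter runs
  when unbiased lags matter.
- Per-record $D_E$ from 60 s differences is noise-hungry; with 1% read
  noise its per-record sd is large and only the window mean is meaningful.
- The desorption model assumes the adsorption isotherm also governs
  re-uptake of the mobile pool; hysteretic sorbents will violate this.
- One reported lag/diffusivity input pair (323 min, 2.34e-10 m²/s) is
  internally inconsistent with $D = L^2/6t_L$ by ~9%; the package computes
  with stated inputs and does not force agreement.
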