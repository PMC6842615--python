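# Methods

## The clonal lineage model

Clones descend from a single labeled radial glial cell (RG) introduced
into culture at a labeling day `t_label` (30 or 40) and observed `t_obs`
days later. The model is a continuous-time Markov branching process over
three cell kinds:

* **RG** divide at rate λ_RG (per day). Before the neurogenic switch time
  `t_switch` (absolute culture days) every RG division is symmetric
  proliferative, RG → RG + RG. From `t_switch` on, each division draws a
  fate: symmetric (probability `p_sym`), asymmetric neurogenic
  RG → RG + IPC (`p_asym`), or differentiative RG → IPC + IPC
  (`p_diff`), with the three probabilities summing to 1.
* **IPC** (intermediate progenitor cells) carry a neurogenic potential —
  a remaining number of division rounds — drawn at birth uniformly from
  {1, …, `k_max`} (a truncated-geometric option exists). They divide at
  rate λ_IPC: terminally, IPC → NEURON + NEURON, with probability
  `p_term` or whenever the potential is exhausted; otherwise
  asymmetrically, IPC → IPC + NEURON, decrementing the potential.
* **NEURON** is terminal.

Waiting times are exponential at the cell's kind-specific rate, so a
clone is simulated event by event (equivalently: a Gillespie simulation
of the cell roster). Every division adds exactly one cell; clone size
equals 1 + number of events, and is non-decreasing in time.

The **mutant condition** is the same model with a single changed
quantity: the weights of the two IPC-producing channels are multiplied
by `diff_multiplier` m ≥ 1 and the fate mix renormalized,

    (p_sym, p_asym, p_diff) → (p_sym, m·p_asym, m·p_diff) / (p_sym + m·(p_asym + p_diff)).

This is the minimal reading of "RGs differentiate into IPCs at a higher
rate": it raises the per-division probability of producing IPCs without
touching division clocks or IPC behavior. An alternative reading — the
differentiative channel as a direct RG → IPC *conversion* (one IPC, no
division) rather than a division channel — is implemented behind
`rg_diff_mode="conversion"`; the division channel is the default because
it preserves the division-event bookkeeping that clone-size data report.

Cell death and quiescence are off by default (live imaging in this
system showed no excess death and negligible quiescence); both are
available as optional rates — death removes the cell, quiescence keeps
it but stops its cycling, after which the observation model scores it
Ki67⁻.

### Oracles

Two independent computations validate the simulator and are used
throughout the tests:

1. **Mean-field means.** Stratifying IPCs by remaining potential makes
   the expected counts obey a linear ODE system, solved exactly by
   matrix exponentials piecewise around `t_switch`. By linearity of
   expectation this is exact for the branching model, with no
   approximation. Monte Carlo compartment means at n = 10,000 clones
   must agree within 3 standard errors.
2. **Embedded fate chain.** Conditional on which cell divides next
   (probability proportional to its rate), fate choice is a discrete
   chain independent of the clock. `enumerate_small_clones` enumerates
   all fate sequences up to 12 events exactly; simulated composition
   frequencies with an event cap must match (chi-square).

A third closed form covers the pre-switch limit: with `t_switch = ∞` the
model is a Yule process and clone size at time t is geometric with
success parameter exp(−λ_RG·t). The test compares CDFs at the integer
support points (the naive one-sample KS applied to a discrete sample
would report the full CDF jump at size 1) and uses the Kolmogorov
asymptotic p-value, which is conservative for discrete data.

## Observation model and summaries

Experiments count, per clone, total cells and Ki67⁺ cells (Ki67 marks
cycling cells; neurons are βIII-tubulin⁺/Ki67⁻). Accordingly cycling RG
and IPC map to Ki67⁺ and everything else to Ki67⁻, with an optional
independent per-cell misclassification rate (default 0 — in this system
nearly all labeled cells expressed exactly one of the two markers).
Clones with fewer than 2 cells are rejected *after* misclassification,
mirroring what an experimenter counts. Cohort summaries comprise mean
clone size and mean Ki67⁺ count (SEM = sample SD/√n), the
all-progenitor / all-neuron / mixed category frequencies, the persisting
fraction (clones with ≥ 1 Ki67⁺ cell — i.e. 1 − freq(all-neuron)),
persisting-clone mean sizes, and integer size histograms on 2…cap with
an overflow bin (cap 32 by default, 16 inside the fitting objective).

The **growth-shape index** distinguishes exponential from linear-like
growth of persisting clones: it is the mean difference of successive
log-mean-size slopes per unit time (0 for exponential growth, negative
for sub-exponential), with an optional case-resampling bootstrap CI when
per-clone sizes are supplied.

## Fitting

The clone-size distribution of this model has no tractable closed form,
so fitting is by simulated summary statistics: for candidate parameters,
cohorts of `n_sim` clones are simulated per design point and reduced to
the same summaries as the data; the loss is the inverse-variance-weighted
sum of squared discrepancies over mean size, mean Ki67⁺ count, persisting
fraction, and histogram bin frequencies. Per-design-point seeds are fixed
across parameter values (common random numbers), which keeps the loss
surface smooth enough for exhaustive grid search; Nelder–Mead refinement
from the grid optimum is optional. Bootstrap CIs use case resampling of
observed clones (200 replicates by default).

`compare_conditions` operationalizes the single-assumption hypothesis:
shared parameters are fitted on control cohorts; the mutant is then
fitted twice — freeing only `diff_multiplier`, and freeing the full
parameter set plus the multiplier — and the hypothesis is accepted if the
one-free-parameter loss is within 5 % (relative) of the all-free loss.
Because the all-free grid contains the one-free optimum, its minimum is
never larger; the comparison therefore needs a low-noise loss
(`n_sim` ≈ 1000), otherwise the minimum over the larger grid picks up
spurious improvements. A misspecified mutant (e.g. a slowed RG division
clock instead of a fate shift) fails this check by an order of magnitude.

## Declared study conditions (generator defaults)

The data-generating defaults play the role of the study's conditions and
were fixed once, by calibrating against the qualitative directions the
experiments report, using the mean-field oracle and moderate-size
simulations:

| parameter | value | rationale |
|---|---|---|
| λ_RG | 0.45 /day | ≈ 2.2-day RG cycle, typical of human cortical progenitors in vitro |
| λ_IPC | 0.6 /day | transit-amplifying cells cycle somewhat faster |
| `t_switch` | 30 days | both labeling days (30, 40) probe the neurogenic phase; the symmetric phase precedes day 30 |
| (`p_sym`, `p_asym`, `p_diff`) | (0.45, 0.20, 0.35) | control RG pool modestly supercritical (p_sym − p_diff = 0.10) |
| `k_max` | 3 | "variable but limited" IPC potential |
| `p_term` | 0.3 | most IPC divisions asymmetric, occasional early terminal division |
| mutant m | 2.0 | doubled differentiation; makes the mutant RG pool subcritical (p_sym′ − p_diff′ ≈ −0.10) |
| cohort sizes | 50–72 (152–176 for histogram cohorts) | the study's reported ranges |

Under these conditions the model reproduces, robustly across seeds at
n = 10,000 clones/point: control Ki67⁺ per clone rising over 2/6/10 dpm
while the mutant's falls; mutant day-40 clone sizes reduced ~30 %;
persisting fractions falling faster in the mutant; and persisting-clone
growth closer to exponential in control than mutant (growth-shape index
higher by ≈ 0.005–0.009). Because `t_switch` coincides with the first
labeling day, day-30 and day-40 cohorts are statistically identical
under the defaults; the switch still matters for any configuration with
`t_switch` between the labeling days.

What the generator does *not* emulate: clone-to-clone heterogeneity
beyond the model (line-to-line variability, culture effects), spatial
structure within clones, marker intensity — only count-level data.
Passing tests therefore demonstrate internal consistency and
recoverability under the model's own assumptions, not the adequacy of
those assumptions for any particular real dataset.

## Rosette model

Dissociated progenitors on a circular 140-µm micropattern field are
point agents with persistent-random-walk motility (speed 10 µm/h,
heading diffusion 0.6 rad per 0.1-h step, radial reflection at the
boundary). Any two agents in different clusters that come within the
attachment radius (8 µm) attach with per-step probability `p_attach`;
attachments are irreversible by default (rosettes are stable at 48 h)
and attached clusters stop moving (a rigid-body diffusion option and a
detachment rate exist but default off). Rosettes are connected
components of the attachment graph with ≥ 3 members (pairs are
incidental contacts, not rosettes); centers are member centroids.

Defaults were calibrated, as a declared design choice rather than a
measured ground truth, so that control-like adhesion yields
predominantly single-rosette fields at 48 h: 8 cells per field and
`p_attach` = 0.1 give a single-rosette fraction ≈ 0.6. The dose-response
of that fraction in `p_attach` rises over roughly [0.001, 0.03] and
saturates above ≈ 0.04 (with frozen irreversible clusters, very high
attachment nucleates several rosettes that can never merge, so the
response is not monotone onto [0, 1] globally); monotonicity checks
therefore sweep the dynamic range up to the control-like default.
Reduced attachment efficiency — the mutant's impaired apical adhesion —
lowers the single-rosette fraction, reproducing the control-vs-mutant
direction.

Rosette-center distance distributions are compared by the two-sample KS
test (scipy); track directionality is the net-displacement-to-path-length
ratio plus the Rayleigh test on net-displacement angles (pingouin), with
the discrete-step persistent-random-walk MSD available in closed form
for validation: E|r_m|² = l²[m(1+a)/(1−a) − 2a(1−a^m)/(1−a)²] with
l = speed·dt and a = exp(−turn_sd²/2).

## Numerical and interface choices

* Per-clone/per-field RNG substreams are derived from
  (master seed, indices) via `numpy.random.SeedSequence`, so cohorts and
  chips are order-independent and exactly reproducible; identical seeds
  share event-sequence prefixes across observation times, which makes
  clone-size monotonicity testable pathwise.
* The enumeration oracle is capped at 12 events (state space growth);
  chi-square comparisons pool cells with expectation < 5.
* Inverse-variance weights are floored (1e-4, and 1/(4n) for
  proportions) to keep the loss finite for degenerate observed
  summaries.
* Grid fits report the full profile; ties resolve to the first grid
  point in iteration order.
* All tables are UTF-8 CSV with headers; parameters, summaries, fits and
  manifests are JSON. Writers never silently overwrite; each CLI run
  writes a manifest (package version, seed, config) sufficient to
  regenerate its outputs byte-identically.

## Known limitations

* Fate probabilities are time-homogeneous after the switch; a gradual
  neurogenic transition is not modeled.
* The mean-field oracle covers the default no-death/no-quiescence model
  only.
* The sufficiency comparison is a point comparison at a declared 5 %
  tolerance, not a formal model-selection test.
* Agents are points; rosette geometry (lumen, apical surface area) and
  mechanics are out of scope, as are image-level data.
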