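# Methods

This note documents the model implemented by `evoweb`, the parameter
choices and their rationale, the numerical decisions, what the scaled-down
experiment design does and does not probe, and known limitations.

## Ecological dynamics

The community consists of a non-evolving basal resource (body mass
$m_0 = 1$, biomass $B_0$) and a set of consumer species, each with fixed
traits $(m_i, f_i, s_i)$: body mass, feeding centre and feeding range.
The feeding kernel $N_{ij}$ is a Gaussian over $\log_{10}$ body mass,
normalised along that axis, centred at $\log_{10} f_i$ with SD $s_i$; the
mass-specific attack rate is $a_{ij} = m_i^{0.75} N_{ij}$.  Because the
kernel is normalised, the peak attack rate scales as $1/s_i$: specialists
are more efficient on their best prey, the built-in efficiency/generalism
trade-off.  Networks are technically fully connected — no attack-rate
cutoff is applied in the dynamics (kernel tails are astronomically small
and cost little at these community sizes); the 10% threshold exists only
in the *realized feeding range* metric.

Consumption follows a Holling type-II functional response whose
half-saturation sum runs over **all** potential prey of the consumer —
the basal resource, every other species, and the consumer itself
(cannibalism; a config switch `include_cannibalism` removes the self term,
and the two-node equilibrium check uses that switch because its closed
form has no self-feeding).  Interference competition between distinct
consumers is $c_{ij} = c_0 I_{ij}/I_{ii}$, where
$I_{ij} = \int N_{ik} N_{jk}\, d(\log_{10} m_k)$ has the closed form of a
product of two Gaussians; the closed form is verified against adaptive
quadrature in the tests.  Competition is a separate mortality term
$-\sum_{j \ne i} c_{ij} B_i B_j$ applied between every ordered pair of
distinct consumers; the basal resource neither competes nor is competed
with.

## Parameters

| symbol | meaning | default |
|---|---|---|
| $n_0$ | basal resource inflow (sets the time scale) | 1.0 |
| $l$ | basal resource outflow | 0.5 |
| $m_0$ | basal resource body mass / mass floor | 1.0 |
| $e$ | assimilation efficiency | 0.85 |
| $c_0$ | interference-competition strength | 0.05 |
| $h_i$ | handling time | $0.4\,m_i^{-0.75}$ |
| $x_i$ | metabolic loss | $0.3\,m_i^{-0.25}$ |
| $a_{ij}$ | attack rate exponent on $m_i$ | 0.75 |
| $p$ | invader probability per introduction | 0.2 |
| $z$ (mutant) | mutant trait-draw SD | 0.1 |
| $z$ (invader) | invader strangeness, the sweep variable | 0.1–5.0 |
| $\varepsilon$ | extinction threshold = introduction biomass | $10^{-8}$ |
| $s$ floor | minimum feeding range | 0.3 |

All rates are relative to $n_0 = 1$; lifespans are therefore in the same
relative time units.

**Handling-time exponent.**  The handling-time allometry is
$h_i = 0.4\,m_i^{-0.75}$, not $m_i^{-0.25}$.  The pairing matters: the
saturated mass-specific intake is $e/(m_i h_i)$, and with the $-0.75$
exponent it scales as $m^{-0.25}$ — the same allometry as metabolic loss —
so the best-case intake-to-metabolism ratio $e/(h_0 x_0) \approx 7.1$ is
independent of body mass.  This is the classic bioenergetic formulation in
which handling time is the reciprocal of a maximum consumption rate set at
a fixed multiple $y = 1/(h_0 x_0) \approx 8$ of metabolism.  With a
$-0.25$ exponent instead, every consumer heavier than
$m = (e/(h_0 x_0))^2 \approx 50$ would starve even on unlimited food, and
the $m = 100$ ancestor that seeds every community could never grow; the
assembly process would be impossible by construction.  The exponent
remains a `Parameters` field for sensitivity work.

## Evolutionary layer

One species is introduced at every multiple of 100 time units up to the
horizon (⌊horizon/100⌋ events; 250,000 at the production horizon of
2.5×10⁷).  Each introduction is an invader with probability $p$, else a
mutant.  Mutant parents are drawn with probability proportional to
individual density $B_i/m_i$; invader parents uniformly.  Child traits are
drawn independently around the parent's: $\log_{10} m$ and $\log_{10} f$
as Normal with SD $z$ (the kernel lives in log-mass space, so trait
novelty is naturally measured there), $s$ as Normal with SD $z$ on the
linear scale.  Floors ($m \ge m_0$, $s \ge 0.3$) are enforced by redraw
rather than clamping, to avoid probability atoms at the boundaries; both
the mutation scale and the floor policy are config switches.  There is no
upper bound on any trait.

New species start at biomass $\varepsilon$; a mutant's seed biomass is
deducted from its parent (total biomass unchanged), an invader's is
injected.  At each 100-step boundary the order of operations is: cull
(strictly $B < \varepsilon$; a species at exactly $\varepsilon$ survives,
matching introduction *at* $\varepsilon$), then introduce, then record —
with all recording excluding the species introduced at that very step.  A
parent pushed below $\varepsilon$ by the mutant deduction is culled at the
next boundary, not immediately.  Culling density is configurable
(`cull_substeps`) for sensitivity checks; the default assesses biomass at
the introduction boundaries.

## Numerical integration

Chunks between introductions are advanced with an adaptive embedded
Runge-Kutta-Fehlberg 4(5) stepper (compiled with numba; the classic
Fehlberg tableau, 5th-order solution propagated, RMS error control with
step factors in [0.2, 5]).  Defaults: rtol $10^{-6}$, atol $10^{-12}$.
Negative excursions — integration noise at the atol scale — are clamped to
zero after each accepted step.  Step-size underflow or a non-finite state
raises a failure that the driver converts into a restart with a fresh
sub-seed; a community-level extinction restarts the same way, and a run
that fails more than `max_restarts` times raises rather than being
silently dropped.  The stepper is validated in the tests against scipy's
LSODA at tight tolerance on live communities, against the analytic
consumer-free solution, and against a root-finder on the two-node
equilibrium conditions.

Randomness: each run derives three independent substreams (introduction
kind, parent selection, trait draws) from `SeedSequence([seed, attempt])`,
making runs bit-reproducible given (config, seed) and the components
independently testable.

## Metrics and statistics

* **Disturbance** — sample SD of the basal-resource and of the summed
  community biomass series (time 0 excluded), and mean species turnover.
  Turnover between consecutive composition snapshots $A, B$ is the Jaccard
  dissimilarity $(|A\setminus B| + |B\setminus A|)/|A\cup B|$: bounded,
  symmetric, zero iff equal.  An asymmetric alternative
  $(\text{gained}+\text{lost})/|A|$ sits behind a flag.
* **Generalism** — mean/median feeding range of *viable mutants* (born
  after the 50,000-step burn-in, survived ≥ 100 steps; invaders excluded
  because the experiment manipulates their traits directly), and the
  realized feeding range: the fraction of community entities (basal
  resource + all extant species, focal included) attacked at ≥ 10% of the
  consumer's maximum attack rate.  The ratio reduces to
  $\exp[-\Delta^2/(2s^2)]$ with $\Delta$ the log-mass distance, so the
  threshold locus is $|\Delta| = s\sqrt{2\ln 10}$; the comparison is
  boundary-inclusive at float precision.
* **Persistence** — lifespan (death − birth time, uncensored species only;
  species alive at the horizon are censored and excluded from all lifespan
  statistics) regressed on $\log_{10} s$ with a gamma GLM (log link); the
  slope sign says whether generalists outlive specialists.  Binned means
  use $s \le 0.32$ (specialist) and $s \ge 0.39$ (generalist),
  intermediates excluded.  "log10-scaled" is read as transforming the
  predictor only — the response already enters through the log link; a
  flag switches to transforming both.

GLM estimation is statsmodels IRLS behind a thin `glm_fit` surface;
quasibinomial is the binomial family with Pearson-χ² dispersion.  Smoothed
additive fits are deliberately not reproduced: across-sweep trends are
certified with Spearman rank correlation (one-sided) plus GLM
coefficients, which carries the monotone-trend content without a smoothing
machinery whose shape parameters would dominate at desk scale.  The
generalist/specialist relative-persistence question uses a Poisson
log-link GLM of mean lifespan on type, $z$ and their interaction.

## Desk-scale experiment design

The production design (horizon 2.5×10⁷, 50 z values × 100 replicates) is
configurable but not what the test suite runs.  The desk profile
(`desk_config`) keeps every model parameter at its reference value and
scales down only the horizon (2×10⁵) and the community-output interval
(2,000 instead of 50,000, so biomass SDs rest on ~100 samples rather
than 4 — chosen on sampling grounds to mirror the ~500 samples per run of
the production cadence).  The turnover interval (10,000), species-data
interval (100) and burn-in (50,000) keep their reference values.  The
acceptance sweep is 10 z values on [0.5, 5.0] × 3 replicates; the region
below z = 0.5 is excluded from trend tests because the assembly process
itself makes low-z behaviour non-monotone.

What the scaled design shows — and does not.  The structural properties
(floors, thresholds, scheduling, equilibria, oracle equivalences) are
scale-free and transfer directly.  The *qualitative trend* results do not
fully transfer: at 1/125 of the production horizon the assembled
communities hold only a handful of coexisting species (interference
competition excludes near-identical specialists, and short horizons limit
trait-space exploration), and with so few species the disturbance metrics
are dominated by single-species swaps.  In the shipped desk-scale runs the
lifespan-slope trend (generalists gaining relative persistence as
strangeness rises) is strongly positive, and the realized-feeding-range
trend is positive; the biomass-SD and turnover trends are weak or absent
at this scale, with exploratory longer-horizon runs suggesting they
strengthen with horizon.  Passing desk-scale trend tests should therefore
be read as evidence about the implementation, not as a substitute for the
production-scale experiment.

## Known limitations

* No spatial structure, adaptive foraging, or environmental drivers;
  traits are fixed for a species' lifetime.
* Lifespans are recorded at 100-step resolution (the culling cadence), so
  lifespan statistics are grid-quantised.
* The restart policy re-seeds an entire run on collapse; at very low z and
  short horizons collapses are rare but possible, and the restart count is
  recorded on the run rather than hidden.
* Checkpoint/resume and cluster orchestration are out of scope; sweeps run
  sequentially in-process.
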