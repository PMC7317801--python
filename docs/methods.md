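# Methods

`wolfdemes` models the Late Pleistocene demography of Northern-Hemisphere
grey wolves from dated mitochondrial genealogies.  This note documents the
model, the numerical and design choices, the synthetic-data generator, and
what the shipped experiments do and do not demonstrate.

## The demographic model

The wolf range is discretised into seven demes separated by major
geographic barriers: Europe, the Middle East, Central North Eurasia, East
Eurasia, Beringia, Arctic North America and continental North America.
Demes form a migration network (nine edges by default; the edge list is a
config value, since the barrier descriptions are verbal rather than
polygon geometry).  Sample-to-deme assignment comes from an explicit
metadata column for the same reason.

Within each deme, genealogies follow a Kingman coalescent scaled so that a
pair of lineages coalesces at rate 1/K, where K (in ky) is the mean
pairwise coalescence time of the deme — proportional to its effective
population size.  Each lineage migrates at total rate m per ky, with the
destination uniform over the deme's neighbours (the model specifies a
per-lineage rate, not a per-edge rate, so a well-connected deme does not
lose lineages faster).  Samples are heterochronous: each lineage enters
the process at its sample's age (ky BP), so ancient samples constrain the
past directly.

Four scenario families share this machinery:

* **static** — constant K, pure drift plus local gene flow (the null);
* **bottleneck** — piecewise K over three epochs, 0–15, 15–40 and >40
  ky BP (K1, K2, K3), changing all demes simultaneously;
* **expansion** — at time T (ky BP) one origin deme starts a range
  expansion that replaces each other deme's indigenous population; a deme
  at hop distance d from the origin is replaced at T − (d−1)·ΔT.
  Backwards in time a replacement is a forced migration of all lineages
  from the replaced deme into a source deme one hop closer to the origin
  (uniformly chosen when several sources exist).  Each replacement is
  preceded (in backwards order) by an instantaneous founder bottleneck;
* **expansion_bottleneck** — both at once.

With seven possible origins this yields 16 scenarios.  Expansion start
times for the two American origins are restricted by the prior to 9–16
ky BP (LGM ice sheets, then post-glacial sea-level rise, block earlier or
later entry); this prior restriction is the only place ice-sheet
geography enters the model.

### The founder bottleneck

The bottleneck's defining property is that any fixed pair of lineages
present in the colonised deme coalesces during it with probability x
(x=1: complete loss of local diversity; x=0: none).  We realise it as an
instantaneous burst of Kingman coalescence of intensity τ = −ln(1−x):
the marginal coalescence time of a tagged pair in a Kingman coalescent is
Exp(1) regardless of how many other lineages are present, so the pair
coalesces within the burst with probability exactly 1 − e^(−τ) = x.  The
burst is one faithful realisation of the stated pairwise law, not the
only one; it is isolated behind `apply_founder_bottleneck` so an
alternative mechanism can be swapped in.

### Engine mechanics

The event loop draws competing exponentials: per-deme coalescence at rate
C(k_d, 2)/K(t) and total migration at rate m·k.  Waiting times are
re-drawn at every structural boundary (sample activation, epoch switch,
colonization); memorylessness makes this exact.  At equal times,
activations are processed before epoch switches, and those before
colonizations; colonization events of one expansion step never chain
within a step because ΔT > 0.  A run that exceeds a time cap without
coalescing raises an error; the cap defaults to 10^4 ky for single
genealogies and to 10^6 ky inside mass ABC simulation, where waits of
thousands of ky between migrations are legitimate at the prior's lower
bound m = 0.001 and a capped draw is simply treated as rejected
(infinite distance).

Two implementations share this definition: a pure-Python engine that
builds full genealogies (`coalescent.simulate_genealogy`), and a numba
kernel (`_kernel`) that skips tree construction and directly accumulates
sums of pairwise TMRCAs per summary-statistic group, which makes the
per-simulation cost independent of the number of tip pairs.  The kernel
uses an inline splitmix64 random stream (deterministic per seed, much
cheaper than a generic generator in a tight loop).  The two paths are
moment-matched against each other in the test suite, and both are checked
against closed forms (serial pair: E[TMRCA] = max(ages) + K; two demes:
E[TMRCA] = 2K same-deme and 2K + 1/(2m) different-deme) and against
msprime configured with matched rates on a three-deme stepping stone.

## Summary statistics

A dated genealogy is reduced to mean pairwise TMRCAs within and between
four groups: Europe (EUR), Middle East (ME), the pooled northeast
Eurasian demes (EAS = Central North Eurasia + East Eurasia + Beringia)
and the pooled Americas (AME).  Pooling affects only the statistics;
structure between pooled demes is still modelled explicitly.  Of the ten
group combinations, the within-ME entry is dropped by default (every
scenario family systematically under-predicts Middle-Eastern deme TMRCA,
and a statistic that no model can fit acts as a pure outlier in the
distance), leaving nine statistics.  Statistic vectors are always named;
subsetting is by name, so observed and simulated vectors cannot be
misaligned.

## ABC

Priors: m log-uniform on [0.001, 20] per ky; K, K1, K2, K3 log-uniform on
[0.01, 100] ky; x uniform on [0, 1]; T uniform on [5, 40] ky BP ([9, 16]
for American origins); ΔT uniform on [0.001, 1] ky.  Each scenario gets
`n_sims` independent draws; every (scenario, draw) pair derives its RNG
seed from the master seed and a hash of the scenario label, so results
are bit-reproducible and independent of execution order or scenario
subsetting.

Distances are squared Euclidean over the nine statistics.  An optional
standardised mode divides each statistic's difference by its standard
deviation over the pooled simulations of all scenarios; it is off by
default.  "Acceptance" keeps the smallest ⌈0.10·n⌉ distances (the
fraction is a config knob), and posterior parameter summaries (median,
IQR, central 95% interval, log10 scale for the log-uniform parameters)
are computed from the accepted draws of a scenario.

Scenario support is summarised by an estimate of each scenario's marginal
likelihood at the observed vector, reported as Bayes factors relative to
the best scenario.  Two estimators are implemented:

* `scenario_likelihood` — a Gaussian product-kernel density of the
  accepted summary vectors evaluated at the observed vector (per-dimension
  Silverman bandwidths, floor bandwidth for degenerate dimensions);
* an ε-ball acceptance-rate estimator — the fraction of a scenario's
  simulations within a common distance ε of the observation, with ε set
  at a small quantile of the pooled distances of all scenarios.  Since ε
  is common, the unknown ball volume cancels from every Bayes factor.

The KDE estimator is the default inside `scenario_likelihood`, but
`run_abc` ranks scenarios with the ε-ball estimator: in nine dimensions
the Silverman bandwidth shrinks only as n^(−1/13), so at desk-scale
simulation counts the kernel is far wider than the differences between
expansion origins and the resulting likelihood ratios are
bandwidth-noise; the acceptance-rate estimator is the classical
rejection-ABC marginal likelihood, its Bayes factors are ratios of
binomial counts with quantifiable error, and it ranks origins far more
stably at equal cost.  Both estimators agree on which scenario families
are rejected outright.

## Synthetic data

The generator replaces the study's real data with draws of known truth:

* **design** — 90 modern + 45 ancient samples by default, allocated to
  demes proportionally to configurable weights (uniform by default,
  largest-remainder rounding); ancient ages uniform on 1–50 ky BP; sample
  coordinates are a per-deme reference point plus Gaussian jitter (4°),
  with longitudes kept on [0, 360) so jitter never wraps.
* **pseudo-observed genealogy** — one draw from a known scenario.  The
  default truth is the regime the study infers for real wolves: expansion
  out of Beringia at T = 25 ky BP, ΔT = 1, strong founder effects
  (x = 0.8), limited gene flow (m = 0.2/ky), and a mid-epoch bottleneck
  (K1, K2, K3 = 2, 0.5, 15 ky — small-and-stable recent sizes, a deep
  LGM trough, a large pre-LGM population).
* **alignment** — finite-sites Jukes–Cantor mutation of the genealogy:
  Poisson(μ·L·branch length) mutations per branch, uniform sites, uniform
  alternative base, over a uniform random root sequence of L = 15,466 bp
  (the control-region-free mitogenome length).  The default rate
  μ = 9×10⁻⁵ /site/ky is a documented placeholder calibrated so the
  default design yields on the order of 8% variable sites (mean total
  tree length ≈ 10³ ky); it is not an estimate of the wolf mitochondrial
  rate.  Finite sites (rather than infinite sites) deliberately allows
  recurrent mutation.

What the generator does **not** emulate: ancient-DNA damage and missing
data, the control region's hypervariability, partition-specific mutation
rates, uneven real-world sampling (the study's samples cluster heavily in
Europe and Beringia), and radiocarbon-calibration uncertainty on ages.
Passing recovery tests on synthetic data therefore shows the inference
machinery is sound at the stated data scale, not that the real-data
conclusions are robust to those unmodelled features.

## Experiment scales

A single mitochondrial genealogy is one draw of a very high-variance
process, so scenario selection needs simulation counts far beyond what a
distance-acceptance step alone suggests.  The shipped experiments use
20,000 simulations per scenario (the study itself used 10⁹ per scenario
on a cluster; 20,000 is the point where desk-scale recovery stabilises),
the full default design of 135 samples, 10% acceptance, and 20
repetitions for the recovery experiments.  Permutation tests default to
10,000 permutations (the study used 10⁶ for AMOVA); both counts are
CLI-tunable.

## Known limitations

* The ε-ball Bayes factors are ratios of small counts when a scenario
  fits poorly; they are reliable for ranking and for order-of-magnitude
  rejection (BF ≤ 0.1), not for fine distinctions among well-fitting
  scenarios — the near-tie between Beringian and East-Eurasian origins is
  real structure (adjacent demes pooled in one statistic group), not an
  artefact.
* Origin identification from a single mitochondrial genealogy is
  realisation-dependent.  Scenario *family* selection (expansion vs the
  static and bottleneck-only nulls) and the posterior of T are stable
  across pseudo-observed data sets, but a given realisation can, by the
  luck of which ancient lineages survive deep, support an origin other
  than the generating one (`analysis/04_recovery_experiment.py`
  quantifies this).  This mirrors the single-marker caveat any
  mitochondria-only analysis carries; multi-locus data, not a larger
  simulation budget, is what would remove it.
* Posterior intervals for T at desk scale are wide (they shrink with
  simulation budget); coverage, not width, is the tested property.
* The colonization timing convention (origin's neighbours replaced at T
  itself) is one of two defensible readings; the alternative
  (neighbours at T − ΔT) is available via a flag.
* Mantel's test and one-level AMOVA are the standard operationalisations
  of "regressed distances" and "variance among demes"; neither handles
  hierarchical structure or partial correlations.
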