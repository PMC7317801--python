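"""Approximate Bayesian Computation: priors, mass simulation, rejection,
scenario likelihoods / Bayes factors and posterior summaries.

Sixteen scenarios are compared: static, bottleneck, expansion out of each
of the seven demes, and expansion+bottleneck out of each of the seven
demes.  For each scenario, parameters are drawn from the prior, one
genealogy is simulated per draw and reduced to the mean-TMRCA summary
vector, and draws within the smallest ``acceptance_fraction`` of squared
Euclidean distances to the observed vector are retained for parameter
posteriors.  Scenario support is measured by each scenario's acceptance
rate within a common distance ball (the classical rejection-ABC marginal
likelihood; the ball volume cancels from every ratio), reported as Bayes
factors relative to the best scenario; a Gaussian product-kernel density
estimate at the observed vector is also provided per scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import FAMILIES
from .demes import DemeGraph, build_default_graph
from .fastsim import BATCH_TIME_CAP_KY, summary_batch
from .samples import SampleSet
from .sumstats import SUMMARY_STATS
from . import fastsim

__all__ = [
    "PriorSpec",
    "DEFAULT_PRIORS",
    "all_scenarios",
    "scenario_label",
    "sample_prior",
    "abc_distance",
    "reject",
    "scenario_likelihood",
    "posterior_summary",
    "ABCResult",
    "run_abc",
]

#: Origins whose expansion start time is restricted to [9, 16] ky BP
#: (LGM ice sheets over North America, then deglacial sea-level rise).
RESTRICTED_T_ORIGINS = ("NorthAmerica", "ArcticNorthAmerica")

#: Parameters sampled (and reported) on a log10 scale.
LOG_SCALE_PARAMS = ("m", "K", "K1", "K2", "K3")


@dataclass(frozen=True)
class PriorSpec:
    """Prior intervals per parameter.

    m and the K parameters are log-uniform over their intervals; x, T and
    dT are uniform.  m is in events per ky; K, T and dT in ky; x is a
    probability.  T is restricted to ``T_american`` for expansions out of
    the American demes.
    """

    m: tuple[float, float] = (0.001, 20.0)
    K: tuple[float, float] = (0.01, 100.0)
    x: tuple[float, float] = (0.0, 1.0)
    T: tuple[float, float] = (5.0, 40.0)
    T_american: tuple[float, float] = (9.0, 16.0)
    dT: tuple[float, float] = (0.001, 1.0)

    def T_range(self, origin: str | None) -> tuple[float, float]:
        if origin in RESTRICTED_T_ORIGINS:
            return self.T_american
        return self.T


DEFAULT_PRIORS = PriorSpec()


def scenario_label(family: str, origin: str | None = None) -> str:
    return f"{family}[{origin}]" if origin else family


def all_scenarios(graph: DemeGraph | None = None) -> list[tuple[str, str | None]]:
    """The 16 (family, origin) scenario combinations."""
    graph = graph or build_default_graph()
    out: list[tuple[str, str | None]] = [("static", None), ("bottleneck", None)]
    out += [("expansion", d) for d in graph.demes]
    out += [("expansion_bottleneck", d) for d in graph.demes]
    return out


def _scenario_key(label: str) -> tuple[int, int]:
    """Stable spawn-key for a scenario, derived from its label (not its
    position in the scenario list, so any execution order or subset
    yields identical per-scenario results)."""
    import hashlib

    h = hashlib.sha256(label.encode()).digest()
    return int.from_bytes(h[:4], "big"), int.from_bytes(h[4:8], "big")


def _loguniform(rng, lo, hi, n):
    return 10 ** rng.uniform(math.log10(lo), math.log10(hi), n)


def sample_prior(
    family: str,
    origin: str | None,
    n: int,
    seed,
    priors: PriorSpec = DEFAULT_PRIORS,
) -> pd.DataFrame:
    """Draw ``n`` parameter vectors from the prior of one scenario.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``;
    reproducible given the same seed.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown scenario family {family!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {"m": _loguniform(rng, *priors.m, n)}
    if family in ("bottleneck", "expansion_bottleneck"):
        for kname in ("K1", "K2", "K3"):
            cols[kname] = _loguniform(rng, *priors.K, n)
    else:
        cols["K"] = _loguniform(rng, *priors.K, n)
    if family in ("expansion", "expansion_bottleneck"):
        if origin is None:
            raise ValueError("expansion families need an origin")
        cols["x"] = rng.uniform(*priors.x, n)
        cols["T"] = rng.uniform(*priors.T_range(origin), n)
        cols["dT"] = rng.uniform(*priors.dT, n)
    return pd.DataFrame(cols)


def abc_distance(sim, obs, stats=None, scales=None) -> np.ndarray | float:
    """Squared Euclidean distance between summary vectors.

    ``sim`` may be a Series/1-D array or a DataFrame/2-D array of many
    simulated vectors; ``obs`` a Series/1-D array.  With ``stats`` the
    named subset is selected (both sides must be named).  ``scales``
    (optional, per-statistic) standardises the differences — off by
    default, matching a plain squared Euclidean distance.  Rows with
    missing entries get an infinite distance; a missing observed entry is
    an error.
    """
    if stats is not None:
        sim = pd.DataFrame(sim)[list(stats)] if np.ndim(sim) == 2 else pd.Series(sim)[list(stats)]
        obs = pd.Series(obs)[list(stats)]
    sim_a = np.asarray(sim, dtype=float)
    obs_a = np.asarray(obs, dtype=float)
    if np.isnan(obs_a).any():
        raise ValueError("observed vector has missing entries; mask them via `stats`")
    diff = sim_a - obs_a
    if scales is not None:
        diff = diff / np.asarray(scales, dtype=float)
    d = np.sum(diff * diff, axis=-1)
    d = np.where(np.isnan(d), np.inf, d)
    return float(d) if np.ndim(d) == 0 else d


def reject(distances, acceptance_fraction: float = 0.10) -> np.ndarray:
    """Boolean acceptance mask of the ceil(fraction*n) smallest distances.

    Ties are broken by draw index (earlier draws first).
    """
    if not 0.0 < acceptance_fraction <= 1.0:
        raise ValueError("acceptance_fraction must be in (0, 1]")
    d = np.asarray(distances, dtype=float)
    n = len(d)
    if n < 10:
        raise ValueError("need at least 10 simulations")
    k = math.ceil(acceptance_fraction * n)
    order = np.argsort(d, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


def scenario_likelihood(
    accepted, obs, bandwidth_floor: float = 1e-3, log: bool = True
) -> float:
    """Marginal-likelihood estimate of one scenario at the observed vector.

    A Gaussian product-kernel density over the accepted summary vectors,
    with per-dimension Silverman bandwidths; zero-variance dimensions get
    ``bandwidth_floor``.  Returns the log density by default (densities
    of badly fitting scenarios underflow in nine dimensions).
    """
    a = np.asarray(accepted, dtype=float)
    o = np.asarray(obs, dtype=float)
    if a.ndim != 2 or a.shape[0] < 20:
        raise ValueError("need >= 20 accepted draws")
    n, d = a.shape
    sd = a.std(axis=0, ddof=1)
    if np.any(sd < bandwidth_floor):
        import warnings

        warnings.warn("(near-)zero-variance summary dimension; using floor bandwidth")
    h = np.maximum(sd, bandwidth_floor) * n ** (-1.0 / (d + 4))
    z = (o[None, :] - a) / h[None, :]
    logk = -0.5 * np.sum(z * z, axis=1) - np.sum(np.log(h)) - 0.5 * d * math.log(2 * math.pi)
    mx = logk.max()
    ll = mx + math.log(np.mean(np.exp(logk - mx)))
    return ll if log else math.exp(ll)


def posterior_summary(accepted_draws: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter posterior quantiles from accepted draws.

    Rows: median, q25, q75 (IQR), lo95, hi95 (central 95% interval), on
    the natural scale; log-scale parameters get an extra ``log10_<name>``
    row.
    """
    if len(accepted_draws) < 20:
        raise ValueError("need >= 20 accepted draws")
    rows = {}
    for col in accepted_draws.columns:
        v = accepted_draws[col].to_numpy(dtype=float)
        rows[col] = {
            "median": np.median(v),
            "q25": np.percentile(v, 25),
            "q75": np.percentile(v, 75),
            "lo95": np.percentile(v, 2.5),
            "hi95": np.percentile(v, 97.5),
        }
        if col in LOG_SCALE_PARAMS:
            lv = np.log10(v)
            rows[f"log10_{col}"] = {
                "median": np.median(lv),
                "q25": np.percentile(lv, 25),
                "q75": np.percentile(lv, 75),
                "lo95": np.percentile(lv, 2.5),
                "hi95": np.percentile(lv, 97.5),
            }
    return pd.DataFrame(rows).T[["median", "q25", "q75", "lo95", "hi95"]]


@dataclass
class ABCResult:
    """Result of a full ABC run over a set of scenarios.

    ``ball_counts`` holds, per scenario, the number of simulations within
    the common distance ``epsilon`` of the observation; Bayes factors are
    ratios of these acceptance rates (the classical rejection-ABC
    marginal-likelihood estimator — the common-ball volume cancels).
    ``log_likelihoods`` holds the Gaussian product-kernel density
    estimates at the observed vector for reference; in nine dimensions
    their bandwidths are too wide at desk-scale simulation counts to rank
    closely competing scenarios reliably (see docs/methods.md).
    """

    obs: pd.Series
    stats: tuple[str, ...]
    seed: int
    n_sims: int
    acceptance_fraction: float
    epsilon: float = float("nan")
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    log_likelihoods: pd.Series = None
    ball_counts: pd.Series = None

    @property
    def bayes_factors(self) -> pd.Series:
        c = self.ball_counts
        return c / c.max()

    @property
    def best(self) -> str:
        return self.ball_counts.idxmax()

    def ranked(self) -> pd.Series:
        return self.bayes_factors.sort_values(ascending=False)

    def accepted_draws(self, label: str) -> pd.DataFrame:
        t = self.tables[label]
        cols = [c for c in t.columns if c not in ("distance", "accepted") and c not in self.stats]
        return t.loc[t["accepted"], cols]

    def posterior(self, label: str) -> pd.DataFrame:
        return posterior_summary(self.accepted_draws(label))


def run_abc(
    obs: pd.Series,
    samples: SampleSet,
    graph: DemeGraph | None = None,
    scenarios=None,
    n_sims: int = 20_000,
    acceptance_fraction: float = 0.10,
    seed: int = 0,
    stats=SUMMARY_STATS,
    priors: PriorSpec = DEFAULT_PRIORS,
    scales=None,
    standardize: bool = False,
    epsilon_quantile: float = 0.005,
    time_cap: float = BATCH_TIME_CAP_KY,
    keep_summaries: bool = False,
) -> ABCResult:
    """Full ABC scenario comparison against an observed summary vector.

    Deterministic given ``seed``: every (scenario, draw) pair gets an
    independent child seed via ``numpy.random.SeedSequence`` spawn keys
    derived from the scenario label, so per-scenario simulations and
    distances do not depend on execution order or on which other
    scenarios are in the run (epsilon, being a pooled quantile, does
    depend on the scenario set).  ``obs`` must be a named summary vector
    covering ``stats``.

    Scenario comparison: a common ball radius epsilon is set at the
    ``epsilon_quantile`` of the pooled distances of all scenarios, and
    each scenario's marginal likelihood is estimated by its acceptance
    rate within that ball; Bayes factors are rate ratios.  Posterior
    parameter summaries use the ``acceptance_fraction`` smallest
    distances per scenario, as does the kernel density reported in
    ``log_likelihoods``.

    With ``standardize=True`` each statistic's difference is divided by
    the statistic's standard deviation over the pooled simulations of all
    scenarios before squaring, so shallow within-group statistics are not
    drowned out by the deep between-group ones.  The default is the plain
    squared Euclidean distance.
    """
    graph = graph or build_default_graph()
    samples.validate_against(graph)
    if scenarios is None:
        scenarios = all_scenarios(graph)
    obs_sel = pd.Series(obs)[list(stats)].astype(float)
    if obs_sel.isna().any():
        raise ValueError("observed vector missing entries for requested stats")

    result = ABCResult(
        obs=obs_sel,
        stats=tuple(stats),
        seed=seed,
        n_sims=n_sims,
        acceptance_fraction=acceptance_fraction,
    )
    per_scenario = []
    for family, origin in scenarios:
        label = scenario_label(family, origin)
        skey = _scenario_key(label)
        prior_seed = np.random.SeedSequence(entropy=seed, spawn_key=(*skey, 0))
        draws = sample_prior(family, origin, n_sims, prior_seed, priors)
        sim_seeds = np.random.SeedSequence(entropy=seed, spawn_key=(*skey, 1)).generate_state(n_sims)
        means, status = summary_batch(
            graph, samples, family, draws, seeds=sim_seeds, origin=origin, time_cap=time_cap
        )
        sim_df = pd.DataFrame(means, columns=fastsim.group_pair_names())
        per_scenario.append((label, draws, sim_df))
    if standardize:
        if scales is not None:
            raise ValueError("give either scales or standardize, not both")
        pool = np.concatenate(
            [s[list(stats)].to_numpy(dtype=float) for _, _, s in per_scenario]
        )
        scales = np.nanstd(pool, axis=0, ddof=1)

    distances = {
        label: abc_distance(sim_df, obs_sel, stats=stats, scales=scales)
        for label, _, sim_df in per_scenario
    }
    pool = np.concatenate(list(distances.values()))
    pool = pool[np.isfinite(pool)]
    if len(pool) == 0:
        raise RuntimeError("no finite distances: every simulation failed")
    epsilon = float(np.quantile(pool, epsilon_quantile))
    result.epsilon = epsilon

    ll = {}
    counts = {}
    for label, draws, sim_df in per_scenario:
        dist = distances[label]
        acc = reject(dist, acceptance_fraction)
        counts[label] = int((dist <= epsilon).sum())
        table = draws.copy()
        table["distance"] = dist
        table["accepted"] = acc
        if keep_summaries:
            table = pd.concat([table, sim_df[list(stats)]], axis=1)
        result.tables[label] = table
        acc_vecs = sim_df.loc[acc, list(stats)].to_numpy(dtype=float)
        # capped draws can be accepted only if fewer than k finite distances
        # exist; their NaN summaries would poison the KDE, so drop them there
        acc_vecs = acc_vecs[~np.isnan(acc_vecs).any(axis=1)]
        ll[label] = scenario_likelihood(acc_vecs, obs_sel.to_numpy())
        result.summaries[label] = posterior_summary(draws.loc[acc])
    result.log_likelihoods = pd.Series(ll)
    result.ball_counts = pd.Series(counts)
    return result
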