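"""Batched summary-statistic simulation (wrapper around the numba kernel).

Given a deme graph, a sample design and a table of parameter draws for
one scenario, simulates every draw and returns the matrix of group-pair
mean TMRCAs.  Numerically follows the same process as
:func:`wolfdemes.coalescent.simulate_genealogy`; see ``_kernel``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._kernel import _simulate_batch
from .coalescent import ScenarioSpec
from .demes import STAT_GROUPS, DemeGraph
from .samples import SampleSet

__all__ = ["group_pair_names", "group_pair_counts", "summary_batch", "simulate_summary"]

#: Raised time cap used for mass simulation (see decisions in docs/methods.md).
BATCH_TIME_CAP_KY = 1e6


def _pidx_matrix(n_groups: int) -> np.ndarray:
    """(g, h) -> flat index over unordered group pairs, g<=h row-major."""
    pidx = np.zeros((n_groups, n_groups), dtype=np.int64)
    c = 0
    for g in range(n_groups):
        for h in range(g, n_groups):
            pidx[g, h] = pidx[h, g] = c
            c += 1
    return pidx


def group_pair_names(groups=STAT_GROUPS) -> list[str]:
    """Names of the flat group-pair axis, e.g. 'EUR-EUR', 'EUR-ME', ..."""
    out = []
    for g in range(len(groups)):
        for h in range(g, len(groups)):
            out.append(f"{groups[g]}-{groups[h]}")
    return out


def group_pair_counts(group_idx: np.ndarray, n_groups: int) -> np.ndarray:
    """Number of unordered tip pairs per group combination."""
    counts = np.bincount(group_idx, minlength=n_groups)
    out = np.zeros(n_groups * (n_groups + 1) // 2)
    c = 0
    for g in range(n_groups):
        for h in range(g, n_groups):
            out[c] = counts[g] * (counts[g] - 1) // 2 if g == h else counts[g] * counts[h]
            c += 1
    return out


def _activation_arrays(samples: SampleSet, graph: DemeGraph):
    ages = samples.ages
    deme_idx = samples.deme_indices(graph)
    group_idx = samples.group_indices(graph)
    order = np.lexsort((np.arange(len(ages)), ages))
    return (
        np.ascontiguousarray(ages[order]),
        np.ascontiguousarray(deme_idx[order]),
        np.ascontiguousarray(group_idx[order]),
        group_idx,
    )


def _flatten(lists) -> tuple[np.ndarray, np.ndarray]:
    off = np.zeros(len(lists) + 1, dtype=np.int64)
    for i, l in enumerate(lists):
        off[i + 1] = off[i] + len(l)
    flat = np.array([v for l in lists for v in l], dtype=np.int64)
    return flat, off


def summary_batch(
    graph: DemeGraph,
    samples: SampleSet,
    family: str,
    draws: pd.DataFrame,
    seeds: np.ndarray,
    origin: str | None = None,
    time_cap: float = BATCH_TIME_CAP_KY,
    neighbors_at_T: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one summary vector per parameter draw.

    ``draws`` columns: m and K (static/expansion) or K1,K2,K3 (bottleneck
    families), plus T, dT, x for the expansion families.  ``seeds`` is a
    per-draw array of RNG seeds (< 2^32).  Returns ``(means, status)``:
    means has one column per group pair (see :func:`group_pair_names`),
    NaN where the design has no pair; status is 0 for clean draws (see
    ``_kernel`` for the other codes), and mean rows of failed draws are
    NaN.
    """
    samples.validate_against(graph)
    n_sims = len(draws)
    if len(seeds) != n_sims:
        raise ValueError("need one seed per draw")
    n_groups = len(STAT_GROUPS)
    adj_flat, adj_off = _flatten(graph.adjacency_lists())
    act_time, act_deme, act_group, group_idx = _activation_arrays(samples, graph)

    has_epochs = family in ("bottleneck", "expansion_bottleneck")
    has_expansion = family in ("expansion", "expansion_bottleneck")
    if has_epochs:
        epoch_times = np.array([0.0, 15.0, 40.0])
        K_draws = draws[["K1", "K2", "K3"]].to_numpy(dtype=float)
    else:
        epoch_times = np.array([0.0])
        K_draws = draws[["K"]].to_numpy(dtype=float)

    if has_expansion:
        if origin is None:
            raise ValueError("expansion families need an origin")
        dist = graph.hop_distances(origin)
        col, src_lists = [], []
        for deme in graph.demes:
            if deme == origin:
                continue
            d = dist[deme]
            hop = d if neighbors_at_T else d + 1
            col.append((graph.index(deme), hop))
            src_lists.append([graph.index(nb) for nb in graph.neighbors(deme) if dist[nb] == d - 1])
        col_deme = np.array([c[0] for c in col], dtype=np.int64)
        col_hop = np.array([c[1] for c in col], dtype=np.int64)
        src_flat, src_off = _flatten(src_lists)
        x_draws = draws["x"].to_numpy(dtype=float)
        T_draws = draws["T"].to_numpy(dtype=float)
        dT_draws = draws["dT"].to_numpy(dtype=float)
        min_hop_steps = max(dist.values()) - 1
        bad = T_draws - min_hop_steps * dT_draws <= 0
        if bad.any():
            raise ValueError("draw(s) with incomplete expansion (colonisation time <= 0)")
    else:
        col_deme = np.zeros(0, dtype=np.int64)
        col_hop = np.zeros(0, dtype=np.int64)
        src_flat, src_off = np.zeros(0, dtype=np.int64), np.zeros(1, dtype=np.int64)
        x_draws = T_draws = dT_draws = np.zeros(n_sims)

    n_pairs = n_groups * (n_groups + 1) // 2
    sums = np.zeros((n_sims, n_pairs))
    status = np.zeros(n_sims, dtype=np.int8)
    _simulate_batch(
        np.ascontiguousarray(seeds, dtype=np.int64),
        graph.n_demes,
        adj_flat,
        adj_off,
        act_time,
        act_deme,
        act_group,
        n_groups,
        len(epoch_times),
        epoch_times,
        np.ascontiguousarray(K_draws),
        draws["m"].to_numpy(dtype=float),
        has_expansion,
        x_draws,
        T_draws,
        dT_draws,
        col_deme,
        col_hop,
        src_flat,
        src_off,
        float(time_cap),
        _pidx_matrix(n_groups),
        sums,
        status,
    )
    counts = group_pair_counts(group_idx, n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts[None, :]
    means[:, counts == 0] = np.nan
    means[status != 0, :] = np.nan
    return means, status


def simulate_summary(
    graph: DemeGraph,
    scenario: ScenarioSpec,
    samples: SampleSet,
    seed: int,
    time_cap: float = BATCH_TIME_CAP_KY,
) -> pd.Series:
    """One draw's group-pair mean TMRCAs as a named Series."""
    draws = pd.DataFrame([scenario.params()])
    means, status = summary_batch(
        graph,
        samples,
        scenario.family,
        draws,
        seeds=np.array([seed]),
        origin=scenario.origin,
        time_cap=time_cap,
    )
    if status[0] != 0:
        from .coalescent import SimulationError

        raise SimulationError(f"simulation failed with status {status[0]}")
    return pd.Series(means[0], index=group_pair_names())
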