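"""Reduce a dated genealogy to mean-TMRCA summary statistics.

Samples are pooled into four groups for summary purposes — EUR (Europe),
ME (Middle East), EAS (central/east Eurasia + Beringia) and AME (the two
American demes) — and the statistic vector holds the mean TMRCA over all
unordered tip pairs within or between groups.  The within-ME entry is
excluded by default (it is systematically under-predicted by every
scenario family and would act as an outlier in the ABC distance), which
leaves nine statistics.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np
import pandas as pd

from .coalescent import Genealogy, pairwise_tmrca
from .demes import STAT_GROUPS, DemeGraph
from .fastsim import group_pair_names
from .samples import SampleSet

__all__ = [
    "ALL_STATS",
    "SUMMARY_STATS",
    "read_dated_tree",
    "summarize",
    "select_stats",
]

#: All ten group combinations.
ALL_STATS = tuple(group_pair_names(STAT_GROUPS))

#: The default nine statistics (within-ME dropped), in canonical order:
#: the three within-group entries, then the six between-group entries.
SUMMARY_STATS = (
    "EUR-EUR",
    "EAS-EAS",
    "AME-AME",
    "EUR-ME",
    "EUR-EAS",
    "EUR-AME",
    "ME-EAS",
    "ME-AME",
    "EAS-AME",
)

#: Age-consistency tolerance (ky) when reading dated trees.
AGE_TOLERANCE_KY = 1e-6


def read_dated_tree(newick: str, metadata: SampleSet | pd.DataFrame,
                    tolerance: float = AGE_TOLERANCE_KY) -> Genealogy:
    """Read a dated genealogy from Newick text (or a file path).

    Branch lengths are in ky; tip ages come from the metadata table
    (columns id, age_ky) and node ages are reconstructed bottom-up.  If
    the paths from two tips imply different ages for a shared ancestor
    beyond ``tolerance``, or any implied age is negative, an error is
    raised.  Tips missing from the metadata are an error; extra metadata
    rows are ignored.
    """
    if isinstance(metadata, SampleSet):
        meta = metadata.table
    else:
        meta = metadata
    if not newick.lstrip().startswith("("):
        with open(newick) as fh:
            newick = fh.read()
    tree = dendropy.Tree.get(
        file=io.StringIO(newick), schema="newick", preserve_underscores=True
    )
    ages_by_id = dict(zip(meta["id"].astype(str), pd.to_numeric(meta["age_ky"])))

    leaves = [lf for lf in tree.leaf_node_iter()]
    tip_ids = [lf.taxon.label for lf in leaves]
    missing = [t for t in tip_ids if t not in ages_by_id]
    if missing:
        raise ValueError(f"tip(s) missing from metadata: {missing}")
    if len(set(tip_ids)) != len(tip_ids):
        raise ValueError("duplicate tip labels in tree")

    # bottom-up ages with consistency check
    node_age: dict[int, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            node_age[id(nd)] = float(ages_by_id[nd.taxon.label])
            continue
        cands = []
        for ch in nd.child_nodes():
            if ch.edge.length is None:
                raise ValueError("tree has a branch without length")
            cands.append(node_age[id(ch)] + float(ch.edge.length))
        if max(cands) - min(cands) > tolerance:
            raise ValueError(
                f"inconsistent node ages: paths imply {min(cands):.6g} vs "
                f"{max(cands):.6g} ky (tolerance {tolerance:g})"
            )
        a = cands[0]
        if a < -tolerance:
            raise ValueError("negative implied node age")
        node_age[id(nd)] = a

    # flatten to array representation (binary trees only)
    n = len(tip_ids)
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    if any(len(nd.child_nodes()) != 2 for nd in internal):
        raise ValueError("genealogy must be strictly binary")
    if len(internal) != n - 1:
        raise ValueError("unexpected node count")
    index = {id(lf): i for i, lf in enumerate(leaves)}
    for j, nd in enumerate(internal):
        index[id(nd)] = n + j
    age = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    for nd in tree.preorder_node_iter():
        age[index[id(nd)]] = node_age[id(nd)]
        for ch in nd.child_nodes():
            parent[index[id(ch)]] = index[id(nd)]
    return Genealogy(tip_ids, age, parent)


def summarize(
    g: Genealogy,
    graph: DemeGraph,
    deme_of: SampleSet | dict | pd.Series,
) -> pd.Series:
    """Mean pairwise TMRCA per group combination.

    ``deme_of`` maps sample id -> deme label (a SampleSet works).
    Returns the full ten-entry vector (named, see :data:`ALL_STATS`);
    combinations with no tip pair are NaN.  Select the modelling subset
    with :func:`select_stats`.
    """
    if g.n_tips == 0:
        raise ValueError("empty genealogy")
    if isinstance(deme_of, SampleSet):
        deme_of = dict(zip(deme_of.ids, deme_of.demes))
    groups = np.array([graph.group_index(deme_of[t]) for t in g.tip_ids])
    tm = pairwise_tmrca(g)
    n_groups = len(STAT_GROUPS)
    sums = np.zeros(n_groups * (n_groups + 1) // 2)
    counts = np.zeros_like(sums)

    def pidx(a, b):
        if a > b:
            a, b = b, a
        return a * n_groups - a * (a - 1) // 2 + (b - a)

    n = g.n_tips
    for i in range(n):
        for j in range(i + 1, n):
            q = pidx(groups[i], groups[j])
            sums[q] += tm[i, j]
            counts[q] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=list(ALL_STATS))


def select_stats(vec: pd.Series, stats=SUMMARY_STATS) -> pd.Series:
    """Reorder/subset a full statistic vector to the modelling subset.

    Raises if a requested entry is missing (flagged NaN) — mask it out of
    ``stats`` explicitly instead.
    """
    sub = vec.reindex(list(stats))
    if sub.isna().any():
        bad = sub.index[sub.isna()].tolist()
        raise ValueError(
            f"summary statistic(s) {bad} undefined for this design; "
            "mask them from the statistic set"
        )
    return sub
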