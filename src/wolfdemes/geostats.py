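"""Isolation by distance and AMOVA on geolocated sequence alignments.

Geographic distances are great-circle (Haversine) kilometres; genetic
distances are the proportion of differing sites between two sequences
under pairwise deletion of missing data.  IBD is quantified by a Mantel
permutation test of the correlation between the two distance matrices;
the fit of the deme scheme is quantified by a single-level analysis of
molecular variance (AMOVA) partitioning squared distances among and
within demes, with significance by permuting deme labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "geographic_distance_matrix",
    "genetic_distance_matrix",
    "mantel_ibd",
    "amova",
    "AmovaResult",
]

EARTH_RADIUS_KM = 6371.0

#: Alignment symbols treated as missing under pairwise deletion.
MISSING_SYMBOLS = frozenset("Nn-?")


def haversine_km(lat1, lon1, lat2, lon2, r: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between two points (degrees).

    G = 2 r arcsin( sqrt( sin^2(dphi/2) + cos(phi1) cos(phi2) sin^2(dlam/2) ) )

    Accepts scalars or arrays; latitudes must be in [-90, 90] and
    longitudes in [-180, 360).
    """
    lat1, lon1, lat2, lon2 = (np.asarray(v, dtype=float) for v in (lat1, lon1, lat2, lon2))
    for la in (lat1, lat2):
        if np.any((la < -90) | (la > 90)):
            raise ValueError("latitude out of range [-90, 90]")
    for lo in (lon1, lon2):
        if np.any((lo < -180) | (lo >= 360)):
            raise ValueError("longitude out of range [-180, 360)")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    out = 2 * r * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def geographic_distance_matrix(lat, lon, ids=None, r: float = EARTH_RADIUS_KM) -> pd.DataFrame:
    """All-pairs Haversine distances (km) as a labelled symmetric matrix."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    m = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :], r=r)
    np.fill_diagonal(m, 0.0)
    if ids is None:
        ids = list(range(len(lat)))
    return pd.DataFrame(m, index=ids, columns=ids)


def _seq_array(sequences) -> tuple[list, np.ndarray]:
    """(ids, uint8 matrix) from {id: seq}, [(id, seq)], or Biopython records."""
    if isinstance(sequences, dict):
        items = list(sequences.items())
    else:
        items = []
        for rec in sequences:
            if hasattr(rec, "seq"):  # SeqRecord
                items.append((rec.id, str(rec.seq)))
            else:
                items.append((rec[0], str(rec[1])))
    ids = [i for i, _ in items]
    lens = {len(s) for _, s in items}
    if len(lens) > 1:
        raise ValueError(f"alignment sequences differ in length: {sorted(lens)}")
    arr = np.frombuffer("".join(s.upper() for _, s in items).encode("ascii"), dtype=np.uint8)
    return ids, arr.reshape(len(ids), -1)


def genetic_distance_matrix(sequences, missing=MISSING_SYMBOLS) -> pd.DataFrame:
    """Pairwise proportion of differing sites, with pairwise deletion.

    For each pair, sites where either sequence is missing (N, -, ? by
    default; case-insensitive) are excluded; the distance is the number
    of mismatches over the number of comparable sites.  A pair with zero
    comparable sites is an error.
    """
    ids, arr = _seq_array(sequences)
    n, L = arr.shape
    miss_codes = {ord(c.upper()) for c in missing} | {ord(c.lower()) for c in missing}
    ok = ~np.isin(arr, list(miss_codes))
    out = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok[i + 1 :]
        comp = both.sum(axis=1)
        if np.any(comp == 0):
            j = int(np.where(comp == 0)[0][0]) + i + 1
            raise ValueError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
        diff = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        out[i, i + 1 :] = out[i + 1 :, i] = diff / comp
    return pd.DataFrame(out, index=ids, columns=ids)


def _as_matrix(d) -> np.ndarray:
    m = np.asarray(pd.DataFrame(d), dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T):
        raise ValueError("distance matrix must be symmetric")
    return m


def mantel_ibd(
    geo,
    gen,
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "pearson",
) -> tuple[float, float]:
    """Mantel test of isolation by distance.

    rho is the correlation (Pearson by default, ``method='spearman'``
    optional) between the upper triangles of the two matrices; the
    one-sided p-value is the proportion of joint row/column permutations
    of one matrix with permuted rho >= observed, with the standard
    +1 correction on both counts.
    """
    g1 = _as_matrix(geo)
    g2 = _as_matrix(gen)
    if g1.shape != g2.shape:
        raise ValueError("matrices must cover the same samples")
    n = g1.shape[0]
    iu = np.triu_indices(n, k=1)

    if method == "spearman":
        from scipy.stats import rankdata

        def vec(m):
            return rankdata(m[iu])
    elif method == "pearson":
        def vec(m):
            return m[iu]
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")

    def corr(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            raise ValueError("constant distance matrix: correlation undefined")
        return float(np.corrcoef(a, b)[0, 1])

    v1 = vec(g1)
    rho = corr(v1, vec(g2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        count += corr(v1, vec(g2[np.ix_(p, p)])) >= rho
    pval = (count + 1) / (n_perm + 1)
    return rho, pval


@dataclass(frozen=True)
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    phi_st: float
    p_value: float | None


def _amova_components(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Variance components from a squared-distance matrix and group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    sizes = np.bincount(codes, minlength=n_groups)
    for gidx in range(n_groups):
        members = np.where(codes == gidx)[0]
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else float("nan")
    n0 = (n - (sizes**2).sum() / n) / df_among
    sigma2_w = ms_within
    sigma2_a = (ms_among - ms_within) / n0
    return ss_among, ss_within, df_among, df_within, sigma2_a, sigma2_w


def amova(gen, grouping, n_perm: int = 10_000, seed: int = 0) -> AmovaResult:
    """Single-level AMOVA from a genetic distance matrix.

    ``grouping`` maps sample id -> group label (dict/Series aligned with
    the matrix labels, or a sequence in matrix order).  Squared pairwise
    distances are partitioned into among- and within-group sums of
    squares; variance components use the standard unequal-sample-size
    coefficient, Phi_ST = sigma2_among / (sigma2_among + sigma2_within),
    and the p-value is the fraction of label permutations with
    Phi_ST >= observed (+1 corrected).  Requires >= 2 groups.
    """
    dm = pd.DataFrame(gen)
    m = _as_matrix(dm)
    ids = list(dm.index)
    if isinstance(grouping, (dict, pd.Series)):
        labels = [grouping[i] for i in ids]
    else:
        labels = list(grouping)
        if len(labels) != len(ids):
            raise ValueError("grouping length mismatch")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    codes = np.array([uniq.index(l) for l in labels])
    d2 = m**2

    ssa, ssw, dfa, dfw, s2a, s2w = _amova_components(d2, codes, len(uniq))
    denom = s2a + s2w
    phi = s2a / denom if denom != 0 else float("nan")
    pct = 100.0 * s2a / denom if denom != 0 else float("nan")

    pval = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            _, _, _, _, ps2a, ps2w = _amova_components(d2, perm, len(uniq))
            pden = ps2a + ps2w
            pphi = ps2a / pden if pden != 0 else float("-inf")
            count += pphi >= phi
        pval = (count + 1) / (n_perm + 1)
    return AmovaResult(
        ss_among=ssa,
        ss_within=ssw,
        df_among=dfa,
        df_within=dfw,
        sigma2_among=s2a,
        sigma2_within=s2w,
        pct_among=pct,
        phi_st=phi,
        p_value=pval,
    )
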