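"""Two-step cluster-based permutation statistics and companions.

The cluster machinery is geometry-agnostic: data are per-subject vectors
over "elements" (channels, channel x time cells, channel pairs, or
time x time decoding cells) plus a symmetric element adjacency.  Step one
computes an elementwise two-sample statistic and thresholds it at a
first-step p of 0.05 (two-sided, positive and negative clusters formed
separately); step two compares each cluster's mass (summed statistic) to
the permutation distribution of the maximum absolute cluster mass.

Also here: Hedges' g with bootstrap CIs, the rank effect size r = z/√N,
the aligned-rank-transform factorial ANOVA, and the continuity-corrected
chi-square comparison of two proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sst

from .layout import SensorLayout

_MASS_TOL = 1e-9


# --------------------------------------------------------------------------
# first-step statistics (vectorized over elements)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unequal-variance t statistic and two-sided p per element (column)."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
        df = np.where(
            (sa + sb) > 0,
            (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1)),
            1.0,
        )
    p = 2 * sst.t.sf(np.abs(t), df)
    return t, p


def mann_whitney_z(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank-sum z statistic (tie-corrected normal approximation).

    Positive z means group ``a`` tends to exceed group ``b``.
    """
    na, nb = a.shape[0], b.shape[0]
    n = na + nb
    both = np.concatenate([a, b], axis=0)
    ranks = sst.rankdata(both, axis=0)
    r1 = ranks[:na].sum(axis=0)
    u1 = r1 - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    # tie correction from the rank multiset (vectorized; ties are rare in
    # continuous data, so columns without ties take the fast path)
    tie_term = np.zeros(both.shape[1])
    srt = np.sort(both, axis=0)
    has_ties = (srt[1:] == srt[:-1]).any(axis=0)
    for col in np.flatnonzero(has_ties):
        _, cnt = np.unique(both[:, col], return_counts=True)
        tie_term[col] = (cnt**3 - cnt).sum()
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma > 0, (u1 - mu) / sigma, 0.0)
    p = 2 * sst.norm.sf(np.abs(z))
    return z, p


def dependent_t(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired t statistic on per-subject differences (columns = elements)."""
    n = d.shape[0]
    m = d.mean(axis=0)
    s = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(s > 0, m / (s / np.sqrt(n)), 0.0)
    p = 2 * sst.t.sf(np.abs(t), n - 1)
    return t, p


def wilcoxon_z(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed-rank z per element, normal approximation with continuity.

    Zero differences are dropped per element (vectorized by ranking |d|
    with zeros pushed out of the ranking).
    """
    n, n_elem = d.shape
    absd = np.abs(d)
    nonzero = absd > 0
    m = nonzero.sum(axis=0)
    # rank only nonzero entries: zeros get +inf so they land at the top,
    # then their ranks are excluded from both W+ and the moments
    ranked = sst.rankdata(np.where(nonzero, absd, np.inf), axis=0)
    wpos = np.where(nonzero & (d > 0), ranked, 0.0).sum(axis=0)
    mu = m * (m + 1) / 4.0
    sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma > 0, (wpos - mu - np.sign(wpos - mu) * 0.5) / sigma, 0.0)
    p = 2 * sst.norm.sf(np.abs(z))
    return z, p


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Scalar Wilcoxon test: exact p for n <= 25 without ties, else normal.

    Returns ``(z, p)`` where z is the continuity-corrected normal-theory
    statistic (used for the effect size r = z/√N).
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0
    z, _ = wilcoxon_z(nz[:, None])
    method = "exact" if (nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size) else "approx"
    p = float(sst.wilcoxon(nz, method=method).pvalue)
    return float(z[0]), p


FIRST_STEP_UNPAIRED = {"welch_t": welch_t, "mann_whitney_z": mann_whitney_z}
FIRST_STEP_PAIRED = {"dependent_t": dependent_t, "wilcoxon_z": wilcoxon_z}


# --------------------------------------------------------------------------
# adjacency constructions


def _neighbor_lists(adjacency) -> list[np.ndarray]:
    if sparse.issparse(adjacency):
        csr = adjacency.tocsr()
        return [csr.indices[csr.indptr[i] : csr.indptr[i + 1]] for i in range(csr.shape[0])]
    adjacency = np.asarray(adjacency, bool)
    return [np.flatnonzero(adjacency[i]) for i in range(adjacency.shape[0])]


def pair_adjacency(layout: SensorLayout) -> tuple[list[tuple[int, int]], sparse.csr_matrix]:
    """Adjacency between channel pairs for pairwise-connectivity clustering.

    Pairs (a,b) and (c,d) are neighbors when they share an electrode and
    the two non-shared electrodes are layout neighbors, or when they are
    disjoint and one of the cross-assignments pairs neighbors with
    neighbors (a~c and b~d, or a~d and b~c).
    """
    n = layout.n_channels
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    A = np.array([p[0] for p in pairs])
    B = np.array([p[1] for p in pairs])
    N = layout.adjacency
    a1, b1 = A[:, None], B[:, None]
    a2, b2 = A[None, :], B[None, :]
    shared = (
        ((a1 == a2) & N[B[:, None], B[None, :]])
        | ((a1 == b2) & N[B[:, None], A[None, :]])
        | ((b1 == a2) & N[A[:, None], B[None, :]])
        | ((b1 == b2) & N[A[:, None], A[None, :]])
    )
    disjoint_ok = (N[A[:, None], A[None, :]] & N[B[:, None], B[None, :]]) | (
        N[A[:, None], B[None, :]] & N[B[:, None], A[None, :]]
    )
    any_shared = (a1 == a2) | (a1 == b2) | (b1 == a2) | (b1 == b2)
    adj = shared | (~any_shared & disjoint_ok)
    np.fill_diagonal(adj, False)
    return pairs, sparse.csr_matrix(adj)


def spatiotemporal_adjacency(layout: SensorLayout, n_times: int) -> sparse.csr_matrix:
    """Channel x time adjacency: consecutive samples within a channel plus
    neighboring channels at the same sample.  Element index = ch * n_times + t."""
    tri = sparse.diags([1, 1], [-1, 1], shape=(n_times, n_times), dtype=bool)
    eye_t = sparse.eye(n_times, dtype=bool)
    eye_c = sparse.eye(layout.n_channels, dtype=bool)
    ch = sparse.csr_matrix(layout.adjacency)
    return (sparse.kron(eye_c, tri) + sparse.kron(ch, eye_t)).tocsr()


def lattice_adjacency(shape: tuple[int, int]) -> sparse.csr_matrix:
    """4-neighborhood adjacency on a 2-D grid (e.g. train-time x test-time)."""
    n0, n1 = shape
    t0 = sparse.diags([1, 1], [-1, 1], shape=(n0, n0), dtype=bool)
    t1 = sparse.diags([1, 1], [-1, 1], shape=(n1, n1), dtype=bool)
    return (
        sparse.kron(t0, sparse.eye(n1, dtype=bool))
        + sparse.kron(sparse.eye(n0, dtype=bool), t1)
    ).tocsr()


# --------------------------------------------------------------------------
# clustering


def _clusters_from_mask(
    mask: np.ndarray, stat: np.ndarray, neighbors: list[np.ndarray]
) -> list[tuple[np.ndarray, float]]:
    """Connected components of supra-threshold same-sign elements."""
    out = []
    for sign in (1, -1):
        active = mask & ((stat > 0) if sign > 0 else (stat < 0))
        idx = np.flatnonzero(active)
        if idx.size == 0:
            continue
        seen = np.zeros(mask.size, bool)
        for start in idx:
            if seen[start]:
                continue
            stack = [start]
            seen[start] = True
            members = []
            while stack:
                e = stack.pop()
                members.append(e)
                for nb in neighbors[e]:
                    if active[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            members = np.array(sorted(members))
            out.append((members, float(stat[members].sum())))
    return out


def _max_mass(clusters: list[tuple[np.ndarray, float]]) -> float:
    return max((abs(m) for _, m in clusters), default=0.0)


@dataclass
class Cluster:
    members: np.ndarray
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    stat: np.ndarray
    stat_name: str
    threshold_p: float
    n_perm: int
    null_max_mass: np.ndarray
    seed: int | None = None
    exact: bool = False

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]

    def to_json_dict(self) -> dict:
        return {
            "stat": self.stat_name,
            "threshold_p": self.threshold_p,
            "n_perm": int(self.n_perm),
            "exact": self.exact,
            "clusters": [
                {
                    "members": [int(m) for m in c.members],
                    "mass": c.mass,
                    "p_value": c.p_value,
                }
                for c in self.clusters
            ],
        }


def cluster_perm(
    data_a: np.ndarray,
    data_b: np.ndarray,
    adjacency,
    first_step: str = "welch_t",
    paired: bool = False,
    threshold_p: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
    exact: bool = False,
) -> ClusterResult:
    """Two-step cluster-based permutation test.

    Unpaired mode permutes group labels; paired mode flips each subject's
    condition sign.  ``exact=True`` (unpaired) enumerates every relabeling
    instead of sampling, and the p-value is then the exact proportion of
    relabelings (including the identity) whose maximal cluster mass reaches
    the observed cluster's mass.
    """
    data_a = np.asarray(data_a, float)
    data_b = np.asarray(data_b, float)
    if data_a.ndim != 2 or data_b.ndim != 2 or data_a.shape[1] != data_b.shape[1]:
        raise ValueError("data must be (subjects, elements) with matching elements")
    n_elem = data_a.shape[1]
    shape = adjacency.shape if hasattr(adjacency, "shape") else (0, 0)
    if shape != (n_elem, n_elem):
        raise ValueError("adjacency does not match the number of elements")
    neighbors = _neighbor_lists(adjacency)

    if paired:
        if data_a.shape[0] != data_b.shape[0]:
            raise ValueError("paired data require equal subject counts")
        if first_step not in FIRST_STEP_PAIRED:
            raise ValueError(f"unknown paired first step {first_step!r}")
        stat_fn = FIRST_STEP_PAIRED[first_step]
        diffs = data_a - data_b
        stat, p = stat_fn(diffs)
    else:
        if data_a.shape[0] < 2 or data_b.shape[0] < 2:
            raise ValueError("need at least 2 subjects per group")
        if first_step not in FIRST_STEP_UNPAIRED:
            raise ValueError(f"unknown first step {first_step!r}")
        stat_fn = FIRST_STEP_UNPAIRED[first_step]
        stat, p = stat_fn(data_a, data_b)

    obs_clusters = _clusters_from_mask(p < threshold_p, stat, neighbors)

    rng = np.random.default_rng(seed)
    na = data_a.shape[0]
    if paired:
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=na)[:, None]
            s, pp = stat_fn(diffs * signs)
            null_max[i] = _max_mass(_clusters_from_mask(pp < threshold_p, s, neighbors))
        denom = n_perm + 1
        extra = 1
    elif exact:
        pooled = np.concatenate([data_a, data_b], axis=0)
        n = pooled.shape[0]
        if comb(n, na) > 200000:
            raise ValueError("too many relabelings for exact enumeration")
        null_max = []
        for idx_a in combinations(range(n), na):
            sel = np.zeros(n, bool)
            sel[list(idx_a)] = True
            s, pp = stat_fn(pooled[sel], pooled[~sel])
            null_max.append(_max_mass(_clusters_from_mask(pp < threshold_p, s, neighbors)))
        null_max = np.array(null_max)
        denom = null_max.size
        extra = 0
    else:
        pooled = np.concatenate([data_a, data_b], axis=0)
        n = pooled.shape[0]
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            s, pp = stat_fn(pooled[perm[:na]], pooled[perm[na:]])
            null_max[i] = _max_mass(_clusters_from_mask(pp < threshold_p, s, neighbors))
        denom = n_perm + 1
        extra = 1

    clusters = [
        Cluster(
            members=members,
            mass=mass,
            p_value=(extra + int((null_max >= abs(mass) - _MASS_TOL).sum())) / denom,
        )
        for members, mass in obs_clusters
    ]
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(
        clusters=clusters,
        stat=stat,
        stat_name=first_step,
        threshold_p=threshold_p,
        n_perm=int(denom if exact else n_perm),
        null_max_mass=np.asarray(null_max),
        seed=seed,
        exact=exact,
    )


# --------------------------------------------------------------------------
# effect sizes


@dataclass
class EffectSize:
    kind: str
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0


def hedges_g(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
    ci: float = 0.95,
) -> EffectSize:
    """Small-sample-corrected standardized mean difference with bootstrap CI.

    g = J * (mean_a - mean_b) / s_pooled with J = 1 - 3 / (4 N - 9).
    The CI resamples subjects within each group (percentile method).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")

    def _g(x, y):
        nx, ny = x.size, y.size
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        if sp2 <= 0:
            raise ValueError("zero pooled variance: effect size undefined")
        J = 1.0 - 3.0 / (4.0 * (nx + ny) - 9.0)
        return J * (x.mean() - y.mean()) / np.sqrt(sp2)

    value = _g(a, b)
    lo = hi = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            xa = a[rng.integers(0, a.size, a.size)]
            xb = b[rng.integers(0, b.size, b.size)]
            try:
                boots[i] = _g(xa, xb)
            except ValueError:
                boots[i] = np.nan
        alpha = (1 - ci) / 2
        lo, hi = np.nanquantile(boots, [alpha, 1 - alpha])
    return EffectSize("hedges_g", float(value), lo, hi, n_boot)


def rank_effect_r(z: float, n: int) -> EffectSize:
    """Rank-test effect size r = z / sqrt(N)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return EffectSize("rank_r", float(z) / np.sqrt(n))


# --------------------------------------------------------------------------
# aligned-rank-transform factorial ANOVA


def art_anova(
    table: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "session",
    subject: str = "subject",
) -> dict[str, dict]:
    """Nonparametric 2x2 mixed factorial ANOVA on aligned, rank-transformed data.

    For each effect (between main, within main, interaction) the responses
    are aligned by stripping the cell-mean contributions of the *other*
    effects, midranked, and submitted to a standard mixed repeated-measures
    ANOVA; only the row for the effect whose alignment was used is kept.
    Returns ``{effect: {"F", "df1", "df2", "p"}}`` with effect keys
    ``between``, ``within`` and ``interaction``.
    """
    import pingouin as pg

    df = table[[subject, between, within, dv]].copy()
    levels_b = sorted(df[between].unique())
    levels_w = sorted(df[within].unique())
    if len(levels_b) != 2 or len(levels_w) != 2:
        raise ValueError("art_anova expects a 2x2 mixed design")
    counts = df.groupby([between, within])[dv].count()
    if len(counts) != 4 or counts.min() < 3:
        raise ValueError("every design cell needs at least 3 observations")

    grand = df[dv].mean()
    mb = df.groupby(between)[dv].mean()
    mw = df.groupby(within)[dv].mean()
    mc = df.groupby([between, within])[dv].mean()
    eff_b = df[between].map(mb) - grand
    eff_w = df[within].map(mw) - grand
    cell = df.set_index([between, within]).index.map(mc)
    eff_int = np.asarray(cell) - np.asarray(eff_b) - np.asarray(eff_w) - grand
    resid = df[dv].to_numpy() - np.asarray(cell)

    aligned = {
        "between": resid + np.asarray(eff_b),
        "within": resid + np.asarray(eff_w),
        "interaction": resid + eff_int,
    }
    source_of = {
        "between": between,
        "within": within,
        "interaction": "Interaction",
    }
    out = {}
    for effect, y in aligned.items():
        if np.ptp(y) == 0:  # degenerate: no variation to test
            out[effect] = {"F": 0.0, "df1": 1.0, "df2": float(len(y) // 2 - 2), "p": 1.0}
            continue
        ranked = df.copy()
        ranked[dv] = sst.rankdata(y)
        aov = pg.mixed_anova(
            data=ranked, dv=dv, within=within, between=between, subject=subject
        )
        row = aov[aov["Source"] == source_of[effect]].iloc[0]
        out[effect] = {
            "F": float(row["F"]),
            "df1": float(row["DF1"]),
            "df2": float(row["DF2"]),
            "p": float(row["p_unc"]),
        }
    return out


# --------------------------------------------------------------------------
# proportions


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> tuple[float, int, float]:
    """Continuity-corrected chi-square test of two proportions (df = 1)."""
    if min(n1, n2) < 1 or not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("invalid counts")
    tab = np.array([[k1, n1 - k1], [k2, n2 - k2]], float)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("empty margin: test undefined")
    res = sst.chi2_contingency(tab, correction=True)
    return float(res.statistic), 1, float(res.pvalue)
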