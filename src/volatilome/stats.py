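"""Distance-based and per-peak statistics for volatilome tables.

Multivariate side: Euclidean distances, one-factor PERMANOVA with permutation
p-values (and exhaustive enumeration for small designs), a rank-sum test of
within- vs between-group distances, and the Mantel test between two distance
matrices. Univariate side: Kruskal-Wallis and one-way ANOVA per peak with
Shapiro/Levene screens, Dunn and Tukey post hocs, and Holm's step-down
multiple-testing adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix, PeakTable


@dataclass
class StatsConfig:
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> "StatsConfig":
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        return self


# -- distances ---------------------------------------------------------------


def euclidean_distances(table: PeakTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample rows."""
    df = table.data if isinstance(table, PeakTable) else table
    if df.isna().to_numpy().any():
        raise ValueError("peak table contains missing values")
    return DistanceMatrix(list(df.index), squareform(pdist(df.to_numpy(), "euclidean")))


# -- PERMANOVA ---------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    df_between: int
    df_within: int
    n_permutations: int
    exhaustive: bool = False


def _permanova_f(d2: np.ndarray, codes: np.ndarray, group_sizes: np.ndarray,
                 ss_total: float) -> tuple[float, float]:
    """Pseudo-F and R^2 for one labelling; ``d2`` is the squared distance matrix."""
    n = d2.shape[0]
    k = len(group_sizes)
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k
    f = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else math.inf
    return f, ss_between / ss_total


def _distinct_label_arrangements(codes: np.ndarray):
    """All distinct arrangements of a label multiset (small n only)."""
    seen: set[tuple[int, ...]] = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.array(perm)


def permanova(d: DistanceMatrix, grouping: Sequence, cfg: StatsConfig | None = None,
              exhaustive: bool = False) -> PermanovaResult:
    """One-factor permutational multivariate analysis of variance.

    Sums of squares are partitioned on the squared distances
    (``SS_total = sum_{i<j} d_ij^2 / n``; within-group terms divided by group
    size); the p-value uses the ``(1 + count) / (1 + B)`` estimator so the floor
    at B=999 is p=0.001. ``exhaustive=True`` enumerates every distinct labelling
    instead (feasible for small n) and reports ``count / total``, the observed
    labelling included.
    """
    cfg = (cfg or StatsConfig()).validate()
    labels = np.asarray([str(g) for g in grouping])
    n = len(d)
    if len(labels) != n:
        raise ValueError("grouping length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.max() == n:
        raise ValueError("a single group contains every sample")
    d2 = d.values ** 2
    ss_total = d2.sum() / (2.0 * n)
    if ss_total == 0:
        raise ValueError("degenerate distances: SS_total is zero")
    f_obs, r2 = _permanova_f(d2, codes, sizes, ss_total)

    if exhaustive:
        count = total = 0
        for perm in _distinct_label_arrangements(codes):
            total += 1
            f_perm, _ = _permanova_f(d2, perm, sizes, ss_total)
            if f_perm >= f_obs - 1e-12:
                count += 1
        p = count / total
        n_perm = total
    else:
        rng = np.random.default_rng(cfg.seed)
        count = 0
        for _ in range(cfg.n_permutations):
            f_perm, _ = _permanova_f(d2, rng.permutation(codes), sizes, ss_total)
            if f_perm >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + cfg.n_permutations)
        n_perm = cfg.n_permutations
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2), p=float(p),
                           df_between=len(uniq) - 1, df_within=n - len(uniq),
                           n_permutations=n_perm, exhaustive=exhaustive)


# -- within/between distances ------------------------------------------------


def within_between_test(d: DistanceMatrix, meta: pd.DataFrame,
                        level: Literal["species", "strain-within-species"] = "species",
                        group_col: str = "species",
                        strain_col: str = "strain") -> tuple[float, float]:
    """One-sided rank-sum test that within-group distances are smaller than
    between-group distances.

    ``level="species"`` compares same-species to different-species sample pairs;
    ``level="strain-within-species"`` compares same-strain (technical) pairs to
    different-strain pairs of the same species.
    Returns the Mann-Whitney U statistic and the one-sided p-value.
    """
    meta = meta.loc[d.ids]
    groups = meta[group_col].to_numpy()
    iu = np.triu_indices(len(d), k=1)
    same_group = groups[iu[0]] == groups[iu[1]]
    dist = d.values[iu]
    if level == "species":
        within = dist[same_group]
        between = dist[~same_group]
    elif level == "strain-within-species":
        strains = meta[strain_col].to_numpy()
        same_strain = strains[iu[0]] == strains[iu[1]]
        within = dist[same_strain & same_group]
        between = dist[~same_strain & same_group]
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(within) == 0 or len(between) == 0:
        raise ValueError("one of the distance partitions is empty; "
                         "need groups with at least 2 members")
    # exact null distribution for small pair sets (ties otherwise force the
    # asymptotic approximation and inflate the minimal attainable p)
    method = "exact" if len(within) + len(between) <= 40 else "auto"
    res = sps.mannwhitneyu(within, between, alternative="less", method=method)
    return float(res.statistic), float(res.pvalue)


# -- Mantel ------------------------------------------------------------------


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, cfg: StatsConfig | None = None,
           exhaustive: bool = False,
           alternative: Literal["two-sided", "greater", "less"] = "two-sided",
           ) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same objects.

    r is the Pearson correlation of the strictly-upper triangles; the p-value
    permutes the row/column order of ``d2`` jointly. ``exhaustive=True``
    enumerates all n! orderings (small n only).
    """
    cfg = (cfg or StatsConfig()).validate()
    if d1.ids != d2.ids:
        if set(d1.ids) != set(d2.ids):
            raise ValueError("distance matrices cover different objects")
        d2 = d2.reorder(d1.ids)
    n = len(d1)
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("degenerate distances: zero variance")
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(d2.values)

    def extreme(r_perm: float) -> bool:
        if alternative == "two-sided":
            return abs(r_perm) >= abs(r_obs) - 1e-12
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        return r_perm <= r_obs + 1e-12

    if exhaustive:
        count = total = 0
        for order in itertools.permutations(range(n)):
            total += 1
            perm = np.array(order)
            if extreme(corr(d2.values[np.ix_(perm, perm)])):
                count += 1
        return r_obs, count / total
    rng = np.random.default_rng(cfg.seed)
    count = 0
    for _ in range(cfg.n_permutations):
        perm = rng.permutation(n)
        if extreme(corr(d2.values[np.ix_(perm, perm)])):
            count += 1
    return r_obs, (1 + count) / (1 + cfg.n_permutations)


# -- univariate battery ------------------------------------------------------


def _split(values: Sequence[float], groups: Sequence) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    return [values[groups == g] for g in np.unique(groups)]


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H (mid-ranks, tie-corrected) and chi-square p-value.

    All-identical data make the tie correction degenerate; by convention H = 0.
    """
    parts = _split(values, groups)
    if len(parts) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate(parts)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*parts)
    return float(h), float(p)


def anova_oneway(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    parts = _split(values, groups)
    if len(parts) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate(parts)
    if np.all(flat == flat[0]):
        return float("nan"), 1.0  # zero variance everywhere: no evidence
    f, p = sps.f_oneway(*parts)
    return float(f), float(p)


def shapiro_per_group(values: Sequence[float], groups: Sequence) -> list[float]:
    """Shapiro-Wilk normality p per group; groups too small (or constant)
    return NaN."""
    out = []
    for part in _split(values, groups):
        if len(part) < 3 or np.all(part == part[0]):
            out.append(float("nan"))
        else:
            out.append(float(sps.shapiro(part).pvalue))
    return out


def levene(values: Sequence[float], groups: Sequence) -> float:
    """Levene homoscedasticity test with group-median centering
    (Brown-Forsythe variant)."""
    parts = _split(values, groups)
    if len(parts) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate(parts)
    if np.all(flat == flat[0]):
        return float("nan")  # no spread anywhere: homoscedasticity is vacuous
    return float(sps.levene(*parts, center="median").pvalue)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm's step-down adjustment: sort ascending, multiply p_(i) by
    (m - i + 1), enforce monotonicity, cap at 1, restore input order."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def dunn_posthoc(values: Sequence[float], groups: Sequence,
                 holm: bool = True) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled mid-ranks with tie correction.

    Returns a symmetric group x group matrix of two-sided p-values (Holm-adjusted
    over all pairs when ``holm=True``); the diagonal is NaN.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(g) for g in groups])
    names = list(np.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    n = len(values)
    ranks = sps.rankdata(values)
    mean_rank = {g: ranks[labels == g].mean() for g in names}
    sizes = {g: int((labels == g).sum()) for g in names}
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    variance_base = n * (n + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        se = math.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        raw.append(2.0 * sps.norm.sf(abs(z)))
    adj = holm_adjust(raw) if holm else np.asarray(raw)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), p in zip(pairs, adj):
        out.loc[a, b] = out.loc[b, a] = float(p)
    return out


def tukey_hsd(values: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """Tukey's HSD pairwise p-value matrix (symmetric, NaN diagonal)."""
    labels = np.asarray([str(g) for g in groups])
    names = list(np.unique(labels))
    parts = _split(values, groups)
    if len(parts) < 2:
        raise ValueError("need at least 2 groups")
    res = sps.tukey_hsd(*parts)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i != j:
                out.loc[a, b] = float(res.pvalue[i, j])
    return out


def univariate_screen(table: PeakTable, meta: pd.DataFrame,
                      group_col: str = "species") -> pd.DataFrame:
    """Per-peak omnibus battery across groups: Kruskal-Wallis, one-way ANOVA,
    Levene (median-centered) and the minimum per-group Shapiro p."""
    meta = meta.loc[table.data.index]
    keep = meta["role"] == "sample" if "role" in meta.columns else np.ones(len(meta), bool)
    groups = meta.loc[keep, group_col]
    data = table.data.loc[groups.index]
    rows = []
    for peak in table.peaks:
        v = data[peak].to_numpy()
        h, kp = kruskal_wallis(v, groups)
        try:
            f, ap = anova_oneway(v, groups)
        except Exception:
            f, ap = float("nan"), float("nan")
        shap = shapiro_per_group(v, groups)
        shap_min = np.nanmin(shap) if not np.all(np.isnan(shap)) else float("nan")
        try:
            lev = levene(v, groups)
        except Exception:
            lev = float("nan")
        rows.append({"peak": peak, "kruskal_H": h, "kruskal_p": kp,
                     "anova_F": f, "anova_p": ap,
                     "levene_p": lev, "shapiro_min_p": shap_min})
    return pd.DataFrame(rows).set_index("peak")
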