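"""Community-ecology statistics.

Hellinger transformation, Bray-Curtis dissimilarity (abundance and binary),
principal coordinates analysis, distance-based redundancy analysis with a
categorical constraint (capscale-style), one-factor PERMANOVA with seeded
permutations, least-squares environmental vector fitting with permutation
p-values, pairwise factor-fit post-hoc tests, and Z-score / collinearity
preprocessing of environmental variables.

Permutation p-values follow the +1 convention, p = (1 + #{perm >= obs}) /
(1 + n_perm), so the attainable minimum with 999 permutations is 0.001.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats

from .io import SchemaError
from .stats import benjamini_hochberg

logger = logging.getLogger("magniche.ordination")


@dataclass
class DistanceMatrix:
    data: pd.DataFrame  # sample x sample, symmetric, zero diagonal
    metric: str

    def __post_init__(self) -> None:
        a = self.data.to_numpy(float)
        if a.shape[0] != a.shape[1]:
            raise SchemaError("distance matrix must be square")
        if np.abs(a - a.T).max() > 1e-10 or np.abs(np.diag(a)).max() > 1e-12:
            raise SchemaError("distance matrix must be symmetric with zero diagonal")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray  # descending, positive axes only
    scores: pd.DataFrame  # sample x axis
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    constrained_inertia: float | None = None
    unconstrained_inertia: float | None = None
    constraint_levels: list[str] | None = None
    n_constrained_axes: int | None = None

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    groups: list[str]
    n: int


def hellinger(abund: pd.DataFrame) -> pd.DataFrame:
    """Square root of within-sample proportions (samples in rows).

    Each row's squared values sum to 1.
    """
    x = abund.to_numpy(float)
    if (x < 0).any():
        raise SchemaError("abundances must be non-negative")
    totals = x.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise SchemaError(f"all-zero sample(s): {[abund.index[i] for i in zero]}")
    return pd.DataFrame(
        np.sqrt(x / totals[:, None]), index=abund.index, columns=abund.columns
    )


def bray_curtis(matrix: pd.DataFrame, binary: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows; binary mode (presence/absence at
    > 0) equals the Sorensen dissimilarity."""
    x = matrix.to_numpy(float)
    if (x < 0).any():
        raise SchemaError("Bray-Curtis requires non-negative data")
    if binary:
        x = (x > 0).astype(float)
    row_sums = x.sum(axis=1)
    if (row_sums == 0).sum() >= 2:
        raise SchemaError("two all-zero samples: Bray-Curtis distance undefined")
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(x, metric="braycurtis")
    )
    return DistanceMatrix(
        data=pd.DataFrame(d, index=matrix.index, columns=matrix.index),
        metric="binary_bray_curtis" if binary else "bray_curtis",
    )


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(d: DistanceMatrix, eps: float = 1e-9) -> OrdinationResult:
    """Principal coordinates analysis via eigendecomposition of the
    Gower-centered matrix. Negative-eigenvalue axes are dropped and reported."""
    n = len(d.ids)
    if n < 3:
        raise SchemaError("PCoA needs at least 3 samples")
    g = _gower_center(d.values)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = eps * max(1.0, abs(eigval[0]))
    pos = eigval > tol
    neg = eigval[eigval < -tol]
    if neg.size:
        logger.info("PCoA: dropped %d negative eigenvalue axes (largest |λ| = %.3g)",
                    neg.size, float(np.abs(neg).max()))
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    # deterministic sign: largest-magnitude loading positive per axis
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] *= -1
    scores = pd.DataFrame(
        coords, index=d.ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    denom = lam.sum() + np.abs(neg).sum()
    return OrdinationResult(
        eigenvalues=lam,
        scores=scores,
        proportion_explained=lam / denom if denom > 0 else lam,
        negative_eigenvalues=neg,
    )


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(labels))
    z = np.column_stack([(labels.to_numpy() == lev).astype(float) for lev in levels])
    return z - z.mean(axis=0), levels


def dbrda(d: DistanceMatrix, constraint: pd.Series | pd.DataFrame) -> OrdinationResult:
    """Distance-based RDA (capscale-style): PCoA coordinates regressed on the
    centered constraint design; eigen-analysis of the fitted component yields
    the constrained axes (≤ levels − 1 for a categorical factor, ≤ number of
    variables for a numeric constraint matrix), the residual the unconstrained
    ones.

    constrained_inertia + unconstrained_inertia equals the total positive PCoA
    inertia (Pythagoras of the orthogonal projection).
    """
    base = pcoa(d)
    x = base.scores.to_numpy(float)
    if isinstance(constraint, pd.DataFrame):
        mat = constraint.loc[d.ids]
        z = mat.to_numpy(float)
        z = z - z.mean(axis=0)
        if np.isnan(z).any():
            raise SchemaError("numeric constraints must be complete (no NA)")
        levels = list(mat.columns)
        max_axes = int(np.linalg.matrix_rank(z))
    else:
        factor = constraint.loc[d.ids]
        if factor.nunique() < 2:
            raise SchemaError("constraint factor must have at least 2 levels")
        z, levels = _indicator(factor)
        max_axes = len(levels) - 1
    # hat matrix of the centered design
    h = z @ np.linalg.pinv(z.T @ z) @ z.T
    fitted = h @ x
    resid = x - fitted

    def eigen_axes(mat: np.ndarray, prefix: str, max_axes: int | None = None):
        u, s, _ = np.linalg.svd(mat, full_matrices=False)
        lam = s**2
        keep = lam > 1e-12 * max(1.0, lam[0] if lam.size else 1.0)
        lam, u, s = lam[keep], u[:, keep], s[keep]
        if max_axes is not None:
            lam, u, s = lam[:max_axes], u[:, :max_axes], s[:max_axes]
        coords = u * s
        for k in range(coords.shape[1]):
            i = np.argmax(np.abs(coords[:, k]))
            if coords[i, k] < 0:
                coords[:, k] *= -1
        return lam, coords

    lam_c, coord_c = eigen_axes(fitted, "CAP", max_axes=max_axes)
    lam_u, coord_u = eigen_axes(resid, "MDS")
    cols = [f"CAP{i + 1}" for i in range(coord_c.shape[1])] + [
        f"MDS{i + 1}" for i in range(coord_u.shape[1])
    ]
    scores = pd.DataFrame(np.hstack([coord_c, coord_u]), index=d.ids, columns=cols)
    return OrdinationResult(
        eigenvalues=np.concatenate([lam_c, lam_u]),
        scores=scores,
        proportion_explained=np.concatenate([lam_c, lam_u]) / base.eigenvalues.sum(),
        negative_eigenvalues=base.negative_eigenvalues,
        constrained_inertia=float((fitted**2).sum()),
        unconstrained_inertia=float((resid**2).sum()),
        constraint_levels=levels,
        n_constrained_axes=coord_c.shape[1],
    )


def _permanova_f(d2: np.ndarray, groups: np.ndarray, group_ids: np.ndarray,
                 sizes: np.ndarray) -> float:
    """Pseudo-F from the distance partition: SS_total = Σ_{i<j} d²/n, SS_within
    from within-group pairwise distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g, size in zip(group_ids, sizes):
        idx = np.where(groups == g)[0]
        if size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(size, 1)].sum() / size
    ss_between = ss_total - ss_within
    a = len(group_ids)
    df_between = a - 1
    df_within = n - a
    if df_within <= 0 or ss_within <= 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def permanova_test(
    d: DistanceMatrix, factor: pd.Series, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-factor PERMANOVA with free permutation of sample labels."""
    factor = factor.loc[d.ids]
    groups = factor.to_numpy()
    group_ids, sizes = np.unique(groups, return_counts=True)
    if len(group_ids) < 2:
        raise SchemaError("PERMANOVA needs at least 2 groups")
    if (sizes == 1).any():
        logger.warning("group(s) with a single sample contribute no within-group SS")
    d2 = d.values**2
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def f_and_ss(g: np.ndarray) -> tuple[float, float]:
        ss_within = 0.0
        for gid in group_ids:
            idx = np.where(g == gid)[0]
            if idx.size < 2:
                continue
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        ss_between = ss_total - ss_within
        a = len(group_ids)
        if n - a <= 0 or ss_within <= 0:
            f = math.inf if ss_between > 0 else 0.0
        else:
            f = (ss_between / (a - 1)) / (ss_within / (n - a))
        return f, ss_between

    f_obs, ss_between = f_and_ss(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = f_and_ss(rng.permutation(groups))
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        r_squared=float(ss_between / ss_total) if ss_total > 0 else 0.0,
        p_value=float(p),
        n_permutations=n_perm,
        groups=list(map(str, group_ids)),
        n=n,
    )


def permanova_exhaustive(d: DistanceMatrix, factor: pd.Series) -> PermanovaResult:
    """Exact permutation p over every distinct relabelling (small n only)."""
    factor = factor.loc[d.ids]
    groups = factor.to_numpy()
    group_ids, sizes = np.unique(groups, return_counts=True)
    d2 = d.values**2
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    f_obs = _permanova_f(d2, groups, group_ids, sizes)

    count = 0
    total = 0
    for perm in set(itertools.permutations(groups)):
        g = np.array(perm)
        f = _permanova_f(d2, g, group_ids, sizes)
        if f >= f_obs - 1e-12:
            count += 1
        total += 1
    ss_between = ss_total - sum(
        d2[np.ix_(np.where(groups == g)[0], np.where(groups == g)[0])][
            np.triu_indices((groups == g).sum(), 1)
        ].sum() / (groups == g).sum()
        for g in group_ids
    )
    return PermanovaResult(
        pseudo_F=float(f_obs), r_squared=float(ss_between / ss_total),
        p_value=count / total, n_permutations=total, groups=list(map(str, group_ids)), n=n,
    )


def envfit(
    ord_result: OrdinationResult,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Least-squares fit of each variable onto the first ``n_axes`` ordination
    axes; r² per variable, permutation p by shuffling the variable across
    samples (+1 convention), BH adjustment across variables."""
    if ord_result.scores.shape[1] < n_axes:
        raise SchemaError(f"ordination has fewer than {n_axes} axes")
    s = ord_result.scores.iloc[:, :n_axes].to_numpy(float)
    s_c = s - s.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = []
    for name in variables.columns:
        v = variables[name].to_numpy(float)
        mask = ~np.isnan(v)
        if mask.sum() < 3:
            logger.warning("envfit: variable %s has < 3 non-missing values; skipped", name)
            continue
        vm = v[mask] - v[mask].mean()
        ss_tot = float(vm @ vm)
        if ss_tot == 0:
            logger.warning("envfit: constant variable %s skipped", name)
            continue
        sm = s_c[mask] - s_c[mask].mean(axis=0)

        def r2_of(vec: np.ndarray) -> tuple[float, np.ndarray]:
            b, *_ = np.linalg.lstsq(sm, vec, rcond=None)
            resid = vec - sm @ b
            return 1.0 - float(resid @ resid) / ss_tot, b

        r2, b = r2_of(vm)
        norm = np.linalg.norm(b)
        direction = b / norm if norm > 0 else b
        count = 0
        for _ in range(n_perm):
            r2p, _ = r2_of(rng.permutation(vm))
            if r2p >= r2 - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        row = {"variable": name, "r_squared": r2, "raw_p": p}
        for k in range(n_axes):
            row[f"axis{k + 1}"] = float(direction[k])
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = benjamini_hochberg(out["raw_p"].to_numpy())
    return out


def pairwise_posthoc(
    scores: pd.DataFrame, factor: pd.Series, n_perm: int = 999, seed: int = 0,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Pairwise factor-fit tests between factor levels on ordination scores.

    For each level pair the statistic is the between-centroid goodness of fit
    r² = SS_between / SS_total of the pair's samples on the first axes, with a
    label-permutation p (+1 convention) and BH adjustment across pairs.
    """
    factor = factor.loc[scores.index]
    levels = sorted(pd.unique(factor))
    if len(levels) < 2:
        raise SchemaError("post-hoc tests need at least 2 levels")
    s = scores.iloc[:, :n_axes].to_numpy(float)
    rng = np.random.default_rng(seed)
    rows = []
    for l1, l2 in itertools.combinations(levels, 2):
        idx = np.where((factor == l1) | (factor == l2))[0]
        if (factor == l1).sum() < 2 or (factor == l2).sum() < 2:
            logger.warning("pair (%s, %s) skipped: fewer than 2 samples in a level", l1, l2)
            continue
        sub = s[idx]
        lab = (factor.iloc[idx] == l1).to_numpy()

        def r2_of(lab_vec: np.ndarray) -> float:
            grand = sub.mean(axis=0)
            ss_tot = float(((sub - grand) ** 2).sum())
            if ss_tot == 0:
                return 0.0
            ss_b = 0.0
            for val in (True, False):
                grp = sub[lab_vec == val]
                ss_b += grp.shape[0] * float(((grp.mean(axis=0) - grand) ** 2).sum())
            return ss_b / ss_tot

        r2 = r2_of(lab)
        count = 0
        for _ in range(n_perm):
            if r2_of(rng.permutation(lab)) >= r2 - 1e-12:
                count += 1
        rows.append(
            {"level_1": l1, "level_2": l2, "r_squared": r2,
             "raw_p": (1 + count) / (1 + n_perm)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = benjamini_hochberg(out["raw_p"].to_numpy())
    return out


def preprocess_env(
    env: pd.DataFrame, r_threshold: float = 0.7
) -> tuple[pd.DataFrame, list[dict]]:
    """Z-score standardize (sample sd, n − 1) and prune collinear variables.

    Columns are visited in input order; a column is removed when its Pearson
    |r| (pairwise-complete observations) strictly exceeds the threshold with
    any already-retained column. Zero-variance columns are removed too. The
    removal log records each removal and its partner.
    """
    removed: list[dict] = []
    retained: list[str] = []
    for col in env.columns:
        v = env[col].to_numpy(float)
        mask = ~np.isnan(v)
        if mask.sum() < 2 or np.nanstd(v, ddof=1) == 0 or np.isnan(np.nanstd(v, ddof=1)):
            removed.append({"variable": col, "reason": "zero_variance", "partner": None})
            continue
        collinear_with = None
        for prev in retained:
            w = env[prev].to_numpy(float)
            both = mask & ~np.isnan(w)
            if both.sum() < 3:
                continue
            r = np.corrcoef(v[both], w[both])[0, 1]
            if np.abs(r) > r_threshold:
                collinear_with = (prev, float(r))
                break
        if collinear_with:
            removed.append(
                {"variable": col, "reason": "collinear",
                 "partner": collinear_with[0], "r": collinear_with[1]}
            )
        else:
            retained.append(col)
    out = env[retained].copy()
    for col in retained:
        v = out[col].to_numpy(float)
        mu = np.nanmean(v)
        sd = np.nanstd(v, ddof=1)
        out[col] = (v - mu) / sd
    return out, removed
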