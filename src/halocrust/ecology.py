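"""Distance-based community ecology with permutation inference.

Implements the battery used to test whether salt-crust communities are
structured by site and moisture: Bray-Curtis dissimilarity, non-metric
multidimensional scaling (NMDS, Kruskal stress-1 with isotonic regression),
the multi-response permutation procedure (MRPP, chance-corrected within-group
agreement A), single-factor PERMANOVA (pseudo-F), BioENV environmental subset
matching (Spearman), and the Mantel test.  All permutation p-values use the
add-one convention p = (count-as-extreme + 1) / (n_permutations + 1), so the
observed statistic is always part of its own null distribution and p is never
zero.  Fixed seeds give identical p-values.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .abundance import AbundanceMatrix
from .config import EcologyParams

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be >= 0")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x k, centered at the origin
    stress: float
    n_starts: int
    converged: bool
    seed: int
    labels: list[str] = field(default_factory=list)


@dataclass
class PermutationTestResult:
    statistic_name: str
    observed: float
    n_permutations: int
    p_value: float
    seed: int
    extras: dict = field(default_factory=dict)


def bray_curtis(matrix: AbundanceMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    d(i, j) = sum |x_ik - x_jk| / sum (x_ik + x_jk); 0 for identical samples,
    1 for disjoint supports.  A pair of all-zero samples is undefined and
    raises with the offending sample names.
    """
    x = matrix.values.to_numpy(dtype=float).T  # samples x organisms
    samples = matrix.samples
    zero = [s for s, row in zip(samples, x) if row.sum() == 0]
    if len(zero) >= 2:
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {zero}")
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            out[i, j] = out[j, i] = np.abs(x[i] - x[j]).sum() / denom
    return DistanceMatrix(labels=list(samples), values=out)


def _stress1(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = (d_config ** 2).sum()
    if denom == 0:
        return 1.0
    return float(np.sqrt(((d_config - disparities) ** 2).sum() / denom))


def nmds(
    d: DistanceMatrix,
    params: EcologyParams = EcologyParams(),
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Each start runs SMACOF-style majorization: configuration distances are
    isotonically regressed on the dissimilarities to get monotone disparities,
    then the Guttman transform updates the configuration; stress-1 is
    non-increasing within a start.  The first start is initialized from
    classical (metric) scaling, the rest randomly; the best final stress is
    reported.  Convergence is declared when the top two starts agree under
    Procrustes alignment.
    """
    n, k = d.n, params.nmds_k
    if k > n - 1:
        raise ValueError(f"nmds_k={k} requires at least {k + 1} samples")
    diss = d.condensed()
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    rng = np.random.default_rng(seed)

    def classical_init() -> np.ndarray:
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d.values ** 2) @ j
        vals, vecs = np.linalg.eigh(b)
        idx = np.argsort(vals)[::-1][:k]
        return vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 1e-12))

    solutions = []
    for start in range(params.nmds_starts):
        if start == 0:
            coords = classical_init()
        else:
            coords = rng.normal(size=(n, k))
        last = np.inf
        for _ in range(params.nmds_max_iter):
            d_conf = pdist(coords)
            if d_conf.max() == 0:
                break
            disp = np.empty_like(d_conf)
            disp[order] = iso.fit_transform(np.arange(len(order)), d_conf[order])
            stress = _stress1(d_conf, disp)
            if last - stress < params.convergence_tol:
                last = stress
                break
            last = stress
            # Guttman transform with disparities
            full_d = squareform(d_conf)
            full_disp = squareform(disp)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(full_d > 0, full_disp / full_d, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            coords = b @ coords / n
        coords = coords - coords.mean(axis=0)
        solutions.append((last if np.isfinite(last) else 1.0, coords))
    solutions.sort(key=lambda t: t[0])
    best_stress, best_coords = solutions[0]
    converged = False
    if len(solutions) > 1:
        converged = _procrustes_disparity(best_coords, solutions[1][1]) < 1e-4
    else:
        converged = True
    if not converged and best_stress > 0.05:
        logger.warning("NMDS starts disagree; returning best-effort solution")
    return OrdinationResult(
        coordinates=best_coords,
        stress=float(min(max(best_stress, 0.0), 1.0)),
        n_starts=params.nmds_starts,
        converged=converged,
        seed=seed,
        labels=list(d.labels),
    )


def _procrustes_disparity(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import procrustes

    try:
        _, _, disparity = procrustes(a, b)
    except ValueError:
        return np.inf
    return float(disparity)


def _within_group_delta(d: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    delta = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        sub = d[np.ix_(idx, idx)]
        mean_within = sub[np.triu_indices(len(idx), k=1)].mean()
        delta += (len(idx) / n) * mean_within
    return delta


def mrpp(
    d: DistanceMatrix,
    groups: list[str],
    params: EcologyParams = EcologyParams(),
    seed: int = 0,
) -> PermutationTestResult:
    """Multi-response permutation procedure.

    delta is the group-size-weighted (n_g / N) mean within-group distance;
    A = 1 - delta_obs / E[delta] with the expectation taken over the
    label-permutation distribution; p is the add-one fraction of permuted
    deltas <= the observed delta.
    """
    labels = np.asarray(groups)
    if len(labels) != d.n:
        raise ValueError("group labels must match matrix labels")
    if len(np.unique(labels)) < 2:
        raise ValueError("MRPP needs >= 2 groups")
    delta_obs = _within_group_delta(d.values, labels)
    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(params.n_permutations)
    for i in range(params.n_permutations):
        perm_deltas[i] = _within_group_delta(d.values, rng.permutation(labels))
    expected = perm_deltas.mean()
    a_stat = 1.0 - delta_obs / expected if expected > 0 else 0.0
    p = (int((perm_deltas <= delta_obs).sum()) + 1) / (params.n_permutations + 1)
    return PermutationTestResult(
        statistic_name="MRPP_A",
        observed=float(a_stat),
        n_permutations=params.n_permutations,
        p_value=float(p),
        seed=seed,
        extras={"delta_observed": float(delta_obs), "delta_expected": float(expected)},
    )


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances and group labels."""
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(
    d: DistanceMatrix,
    factor: list[str],
    params: EcologyParams = EcologyParams(),
    seed: int = 0,
) -> PermutationTestResult:
    """Single-factor PERMANOVA (Adonis-style) with label permutation."""
    labels = np.asarray(factor)
    if len(labels) != d.n or d.n < 4:
        raise ValueError("factor must match matrix labels, n >= 4")
    if len(np.unique(labels)) < 2:
        raise ValueError("factor needs >= 2 levels")
    for g in np.unique(labels):
        if (labels == g).sum() < 1:
            raise ValueError(f"level {g!r} has no members")
    d2 = d.values ** 2
    f_obs, r2 = _permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(params.n_permutations):
        f_perm, _ = _permanova_f(d2, rng.permutation(labels))
        if f_perm >= f_obs:
            count += 1
    p = (count + 1) / (params.n_permutations + 1)
    return PermutationTestResult(
        statistic_name="PERMANOVA_pseudo_F",
        observed=float(f_obs),
        n_permutations=params.n_permutations,
        p_value=float(p),
        seed=seed,
        extras={"R2": float(r2)},
    )


@dataclass
class BioEnvResult:
    best_subset: tuple[str, ...]
    correlation: float
    all_subsets: pd.DataFrame


def bioenv(
    d: DistanceMatrix,
    env: pd.DataFrame,
    params: EcologyParams = EcologyParams(),
) -> BioEnvResult:
    """Exhaustive BioENV search over environmental variable subsets.

    Variables are z-scored (constants dropped with a warning); for every
    non-empty subset the Euclidean environmental distance is rank-correlated
    (Spearman) with the community dissimilarity; the subset maximizing the
    correlation wins (ties to the smaller subset, then lexicographic).
    """
    missing = [s for s in d.labels if s not in env.index]
    if missing:
        raise ValueError(f"env table missing samples: {missing}")
    env = env.loc[d.labels]
    cols = []
    for col in env.columns:
        if env[col].nunique() <= 1:
            warnings.warn(f"dropping constant variable {col!r}", stacklevel=2)
            continue
        cols.append(col)
    if not cols:
        raise ValueError("no non-constant environmental variables")
    if len(cols) > 12:
        raise ValueError("bioenv subset search limited to 12 variables")
    z = env[cols].astype(float)
    if params.standardize_env:
        z = (z - z.mean()) / z.std(ddof=1)
    target = rankdata(d.condensed())
    rows = []
    for size in range(1, len(cols) + 1):
        for subset in itertools.combinations(cols, size):
            env_d = pdist(z[list(subset)].to_numpy())
            rho = _pearson(rankdata(env_d), target)
            rows.append({"subset": subset, "size": size, "rho": rho})
    table = pd.DataFrame(rows)
    best = table.loc[
        table.sort_values(
            by=["rho", "size", "subset"], ascending=[False, True, True]
        ).index[0]
    ]
    return BioEnvResult(
        best_subset=tuple(best["subset"]),
        correlation=float(best["rho"]),
        all_subsets=table,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if denom == 0:
        raise ValueError("zero variance in correlation input")
    return float((x * y).sum() / denom)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    params: EcologyParams = EcologyParams(),
    seed: int = 0,
    method: str = "pearson",
) -> PermutationTestResult:
    """Mantel test of matrix correlation.

    r is the Pearson (or Spearman, via ``method``) correlation of the
    condensed off-diagonal entries; the null permutes rows and columns of the
    second matrix simultaneously; p is one-sided (r_perm >= r_obs, add-one).
    """
    if d1.labels != d2.labels:
        raise ValueError("matrices must share labels in the same order")
    x = d1.condensed()
    y = d2.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance off-diagonal entries")
    if method == "spearman":
        x = rankdata(x)

        def corr(yv: np.ndarray) -> float:
            return _pearson(x, rankdata(yv))
    elif method == "pearson":
        def corr(yv: np.ndarray) -> float:
            return _pearson(x, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    n = d2.n
    count = 0
    for _ in range(params.n_permutations):
        perm = rng.permutation(n)
        y_perm = squareform(d2.values[np.ix_(perm, perm)], checks=False)
        if corr(y_perm) >= r_obs:
            count += 1
    p = (count + 1) / (params.n_permutations + 1)
    return PermutationTestResult(
        statistic_name=f"Mantel_r_{method}",
        observed=float(r_obs),
        n_permutations=params.n_permutations,
        p_value=float(p),
        seed=seed,
    )
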