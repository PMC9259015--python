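"""Cluster-based permutation (CBP) inference and FDR control.

Pointwise statistics (paired t, one-sample t, or Spearman rho against a
per-subject covariate) are thresholded at a cluster-forming alpha per
tail, contiguous supra-threshold points are clustered (1-D contiguity in
time, 4-neighborhood in time-frequency grids), and each observed cluster's
summed statistic is compared against a null distribution built by
within-subject sign flips (contrasts) or covariate permutation
(correlations), retaining the maximum cluster-level statistic of each
permutation.  p-values use the (+1) convention, so the smallest attainable
p is 1/(n_perm + 1); with ``exact=True`` all 2^n sign assignments are
enumerated instead and p is the exact tail fraction.

Positive and negative tails are tested as two separate one-tailed
families at the configured alpha each (0.025 per tail by default, i.e.
0.05 two-sided family-wise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "PermutationConfig",
    "Cluster",
    "ClusterResult",
    "cbp_paired",
    "cbp_one_sample",
    "cbp_correlation",
    "fdr_correct",
]


@dataclass
class PermutationConfig:
    n_perm: int = 500
    alpha: float = 0.025  # cluster-forming threshold, per tail
    seed: int | None = 0
    exact: bool = False  # enumerate all sign flips (contrasts only)

    def __post_init__(self) -> None:
        if not self.exact and self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")


@dataclass
class Cluster:
    indices: np.ndarray  # flat indices into the grid
    stat: float  # summed pointwise statistic
    p: float
    sign: int  # +1 / -1 tail
    effect_size: float  # Cohen's d (contrasts) or mean rho (correlations)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    stat_map: np.ndarray  # pointwise t or rho, grid-shaped
    threshold: float
    shape: tuple

    def significant(self, alpha_per_tail: float = 0.025) -> list[Cluster]:
        """Clusters significant in their one-tailed family (0.025 per tail
        for a 0.05 two-sided family-wise level)."""
        return [c for c in self.clusters if c.p < alpha_per_tail]

    def mask(self, alpha_per_tail: float = 0.025) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for c in self.clusters:
            if c.p < alpha_per_tail:
                m.flat[c.indices] = True
        return m


def _label_clusters(supra: np.ndarray):
    """Contiguous clusters: 1-D runs, or 4-neighborhood on 2-D grids."""
    if supra.ndim == 1:
        structure = np.ones(3, dtype=bool)
    else:
        structure = ndimage.generate_binary_structure(supra.ndim, 1)
    labels, n = ndimage.label(supra, structure=structure)
    return labels, n


def _cluster_sums(stat_map: np.ndarray, supra: np.ndarray):
    labels, n = _label_clusters(supra)
    if n == 0:
        return [], labels
    sums = ndimage.sum_labels(stat_map, labels, index=np.arange(1, n + 1))
    return list(sums), labels


def _max_cluster_stat(stat_row: np.ndarray, thresh: float, sign: int) -> float:
    """Largest |summed stat| among clusters in one tail (0 if none)."""
    supra = stat_row > thresh if sign > 0 else stat_row < -thresh
    sums, _ = _cluster_sums(stat_row, supra)
    if not sums:
        return 0.0
    return max(abs(s) for s in sums)


def _t_from_signs(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for many sign assignments at once.

    diffs: (n_sub, n_points); signs: (n_perm, n_sub). The second moment of
    the flipped data is sign-invariant, so only the mean varies.
    """
    n = diffs.shape[0]
    m2 = np.mean(diffs**2, axis=0)  # (n_points,)
    means = signs @ diffs / n  # (n_perm, n_points)
    var = (m2[None, :] - means**2) * n / (n - 1)
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / n)


def _sign_matrix(cfg: PermutationConfig, n_sub: int) -> np.ndarray:
    if cfg.exact:
        if n_sub > 20:
            raise ValueError("exact enumeration limited to n <= 20 subjects")
        bits = np.arange(2**n_sub)[:, None] >> np.arange(n_sub)[None, :]
        return np.where(bits & 1, 1.0, -1.0)
    rng = np.random.default_rng(cfg.seed)
    return rng.choice([-1.0, 1.0], size=(cfg.n_perm, n_sub))


def _assemble(
    stat_map: np.ndarray,
    thresh: float,
    null_max: dict[int, np.ndarray],
    n_null: int,
    exact: bool,
    effect_fn,
) -> ClusterResult:
    """Build the result; each tail is its own one-tailed family with its
    own max-cluster-statistic null distribution."""
    shape = stat_map.shape
    flat = stat_map.ravel()
    clusters: list[Cluster] = []
    for sign in (+1, -1):
        supra = flat > thresh if sign > 0 else flat < -thresh
        labels, n = _label_clusters(supra.reshape(shape))
        null = null_max[sign]
        for lab in range(1, n + 1):
            idx = np.flatnonzero(labels.ravel() == lab)
            s = float(flat[idx].sum())
            # tiny relative tolerance so the identity permutation always
            # counts itself despite float round-off
            cut = abs(s) * (1 - 1e-12)
            if exact:
                p = float(np.mean(null >= cut))
            else:
                p = float((1 + np.sum(null >= cut)) / (n_null + 1))
            clusters.append(
                Cluster(
                    indices=idx,
                    stat=s,
                    p=p,
                    sign=sign,
                    effect_size=float(effect_fn(idx)),
                )
            )
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(
        clusters=clusters, stat_map=stat_map, threshold=thresh, shape=shape
    )


def _cbp_signflip(diffs: np.ndarray, cfg: PermutationConfig) -> ClusterResult:
    diffs = np.asarray(diffs, dtype=float)
    n_sub = diffs.shape[0]
    shape = diffs.shape[1:]
    if n_sub < 6:
        raise ValueError("need at least 6 subjects")
    flat = diffs.reshape(n_sub, -1)
    degenerate = np.isclose(flat.std(axis=0), 0)
    if np.any(degenerate & ~np.isclose(flat.mean(axis=0), 0)):
        raise ValueError("constant nonzero difference: t statistic undefined")

    with np.errstate(invalid="ignore", divide="ignore"):
        t_obs = stats.ttest_1samp(flat, 0.0, axis=0).statistic
    t_obs = np.where(degenerate, 0.0, t_obs).reshape(shape)
    thresh = float(stats.t.ppf(1 - cfg.alpha, n_sub - 1))

    signs = _sign_matrix(cfg, n_sub)
    t_null = _t_from_signs(flat, signs)
    null_max = {
        s: np.array(
            [_max_cluster_stat(row.reshape(shape), thresh, s) for row in t_null]
        )
        for s in (+1, -1)
    }

    def cohens_d(idx):
        x = flat[:, idx].mean(axis=1)
        return x.mean() / x.std(ddof=1) if x.std(ddof=1) > 0 else 0.0

    return _assemble(t_obs, thresh, null_max, len(signs), cfg.exact, cohens_d)


def cbp_paired(
    data_a: np.ndarray, data_b: np.ndarray, cfg: PermutationConfig | None = None
) -> ClusterResult:
    """Paired-contrast CBP test on subject x grid arrays.

    The null is built by flipping each subject's condition assignment
    (sign of the within-subject difference), retaining the maximum
    cluster-level summed t per permutation.
    """
    cfg = cfg or PermutationConfig()
    a, b = np.asarray(data_a, float), np.asarray(data_b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return _cbp_signflip(a - b, cfg)


def cbp_one_sample(data: np.ndarray, cfg: PermutationConfig | None = None) -> ClusterResult:
    """One-sample CBP test against zero (sign flips of subject values)."""
    cfg = cfg or PermutationConfig()
    return _cbp_signflip(np.asarray(data, float), cfg)


def _rank(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(x, axis=axis)


def cbp_correlation(
    data: np.ndarray, covariate: np.ndarray, cfg: PermutationConfig | None = None
) -> ClusterResult:
    """CBP on pointwise Spearman correlation with a per-subject covariate.

    The cluster-forming threshold on rho comes from the t-approximation at
    the configured alpha; the null permutes the covariate across subjects.
    """
    cfg = cfg or PermutationConfig()
    data = np.asarray(data, float)
    cov = np.asarray(covariate, float)
    n_sub = data.shape[0]
    shape = data.shape[1:]
    if n_sub < 10:
        raise ValueError("need at least 10 subjects")
    if cov.shape != (n_sub,):
        raise ValueError("covariate must be one value per subject")
    if np.ptp(cov) == 0:
        raise ValueError("constant covariate")

    flat = data.reshape(n_sub, -1)
    rd = _rank(flat, axis=0)
    rd = rd - rd.mean(axis=0)
    norm = np.sqrt((rd**2).sum(axis=0))
    norm[norm == 0] = np.inf
    rd /= norm
    u = _rank(cov)
    u = u - u.mean()
    u /= np.sqrt((u**2).sum())

    rho_obs = (u @ rd).reshape(shape)
    tcrit = stats.t.ppf(1 - cfg.alpha, n_sub - 2)
    thresh = float(tcrit / np.sqrt(n_sub - 2 + tcrit**2))

    rng = np.random.default_rng(cfg.seed)
    perms = np.array([rng.permutation(n_sub) for _ in range(cfg.n_perm)])
    rho_null = u[perms] @ rd  # (n_perm, n_points)
    null_max = {
        s: np.array(
            [_max_cluster_stat(row.reshape(shape), thresh, s) for row in rho_null]
        )
        for s in (+1, -1)
    }

    def mean_rho(idx):
        return rho_obs.ravel()[idx].mean()

    return _assemble(rho_obs, thresh, null_max, cfg.n_perm, False, mean_rho)


def fdr_correct(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up within one family of tests.

    Returns ``(adjusted_p, reject)``; adjusted p-values are monotone
    nondecreasing in the raw ranks.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
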