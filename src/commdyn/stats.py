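"""Supporting community statistics.

Hellinger standardization, Bray-Curtis and Sorensen dissimilarities, the
Mantel permutation test, and a (modified) signed-likelihood-ratio test for
the equality of coefficients of variation across groups — the test used to
compare salinity/temperature variability between stations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import squareform

from .data_io import CommunityMatrix, PresenceMatrix

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "SLRTResult",
    "hellinger",
    "bray_curtis",
    "sorensen",
    "mantel",
    "cv_slrt",
]


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample labels."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, CommunityMatrix):
        return data.counts.astype(float), data.sample_ids
    if isinstance(data, PresenceMatrix):
        return data.presence.astype(float), data.sample_ids
    arr = np.asarray(data, dtype=float)
    return arr, [f"s{j}" for j in range(arr.shape[1])]


def hellinger(data) -> np.ndarray:
    """Hellinger standardization: square roots of relative abundances.

    Each sample (column) is divided by its total and square-rooted, so the
    squared entries of every column sum to 1; the transform is invariant
    to per-sample sequencing effort.
    """
    x, _ = _as_matrix(data)
    totals = x.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cannot Hellinger-transform all-zero sample(s)")
    return np.sqrt(x / totals)


def bray_curtis(data) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples (columns).

    ``BC(a, b) = 1 - 2 * sum(min(a_i, b_i)) / (sum a + sum b)``; entries
    between two empty samples are undefined and set to NaN.
    """
    x, ids = _as_matrix(data)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = x.sum(axis=0)
    n = x.shape[1]
    d = np.zeros((n, n))
    for a in range(n):
        mins = np.minimum(x[:, a : a + 1], x[:, a + 1 :]).sum(axis=0)
        denom = totals[a] + totals[a + 1 :]
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(denom > 0, 1.0 - 2.0 * mins / denom, np.nan)
        d[a, a + 1 :] = row
        d[a + 1 :, a] = row
    return DistanceMatrix(d, list(ids))


def sorensen(pm: PresenceMatrix) -> DistanceMatrix:
    """Sorensen dissimilarity: Bray-Curtis on presence-absence,
    ``1 - 2|A and B| / (|A| + |B|)``."""
    return bray_curtis(pm)


@dataclass
class MantelResult:
    """Pearson Mantel correlation with permutation significance."""

    r: float
    p: float                # one-sided (positive association)
    p_two_sided: float
    n_perm: int
    degenerate: bool = False


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices.

    ``r`` correlates the upper-triangle entries; the null distribution is
    built by simultaneously permuting rows and columns of ``d2``.  The
    primary p-value is one-sided for positive association with the
    add-one convention; a two-sided p is reported as well.  Matrices with
    zero variance in either triangle are flagged degenerate (r undefined,
    p = 1).
    """
    if d1.n != d2.n:
        raise ValueError("distance matrices must match in size")
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("distance matrices must share sample_ids")
    n = d1.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    m2 = d2.values
    v2 = m2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        return MantelResult(np.nan, 1.0, 1.0, 0, degenerate=True)
    # correlation via centered residuals; reused across permutations
    c1 = v1 - v1.mean()
    denom1 = np.sqrt(np.sum(c1**2))
    def corr(mat):
        v = mat[iu]
        c = v - v.mean()
        s = np.sqrt(np.sum(c**2))
        return float(np.sum(c1 * c) / (denom1 * s)) if s > 0 else np.nan
    r_obs = corr(m2)
    rng = np.random.default_rng(seed)
    ge = ge_abs = n_eff = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(m2[np.ix_(perm, perm)])
        if np.isnan(r_p):
            continue
        n_eff += 1
        if r_p >= r_obs - 1e-12:
            ge += 1
        if abs(r_p) >= abs(r_obs) - 1e-12:
            ge_abs += 1
    return MantelResult(
        r=r_obs,
        p=(1 + ge) / (n_eff + 1),
        p_two_sided=(1 + ge_abs) / (n_eff + 1),
        n_perm=n_eff,
    )


# ---------------------------------------------------------------------------
# Modified signed-likelihood ratio test for CV equality
# ---------------------------------------------------------------------------


@dataclass
class SLRTResult:
    """CV-equality likelihood-ratio test result."""

    statistic: float
    df: int
    p_asymptotic: float
    p_sim: float | None
    n_sim: int
    cvs: np.ndarray            # per-group sample CVs
    common_cv: float           # common-CV MLE under the null


def _profile_mu(xbar, v, tau):
    """Common-CV normal model: closed-form group mean MLE at fixed tau."""
    t2 = tau * tau
    return (-xbar + np.sqrt(xbar * xbar + 4.0 * t2 * (v + xbar * xbar))) / (2.0 * t2)


def _slrt_statistic(xbar, v, nu):
    """LR statistic for CV equality from sufficient statistics.

    ``xbar``/``v`` have shape (..., k): group means and (small-sample
    adjusted, divisor nu) variances; ``nu`` are effective group sizes.
    The common CV is profiled out by golden-section search on log tau.
    Returns ``(statistic, tau_hat)`` broadcast over leading axes.
    """
    ll1 = np.sum(-0.5 * nu * np.log(v) - 0.5 * nu, axis=-1)

    def ll0(log_tau):
        tau = np.exp(log_tau)
        mu = _profile_mu(xbar, v, tau[..., None])
        resid = v + (xbar - mu) ** 2
        return np.sum(
            -nu * (log_tau[..., None] + np.log(mu)) - nu * resid / (2.0 * (tau[..., None] * mu) ** 2),
            axis=-1,
        )

    cv0 = np.sqrt(np.sum(nu * v, axis=-1) / np.sum(nu * xbar * xbar, axis=-1))
    lo = np.log(cv0) - 4.0
    hi = np.log(cv0) + 4.0
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc, fd = ll0(c), ll0(d)
    for _ in range(70):
        go_right = fc < fd
        a = np.where(go_right, c, a)
        b = np.where(go_right, b, d)
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc, fd = ll0(c), ll0(d)
    log_tau = 0.5 * (a + b)
    stat = 2.0 * (ll1 - ll0(log_tau))
    return np.maximum(stat, 0.0), np.exp(log_tau)


def cv_slrt(groups, n_sim: int = 1000, seed: int = 0) -> SLRTResult:
    """Test equality of coefficients of variation across normal samples.

    Likelihood-ratio test of a common CV (sigma_i = tau * mu_i) against
    group-specific CVs, with a small-sample modification (effective sizes
    n_i - 1 and matching variance divisors) applied to the signed-root
    construction.  ``p_asymptotic`` refers the statistic to chi-square with
    k - 1 degrees of freedom; the primary ``p_sim`` is a parametric
    bootstrap under the fitted common-CV model with ``n_sim`` simulation
    runs.  Requires >= 2 groups of >= 3 positive-mean observations each.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([len(g) for g in groups], dtype=float)
    if np.any(n < 3):
        raise ValueError("each group needs at least 3 observations")
    xbar = np.array([g.mean() for g in groups])
    if np.any(xbar <= 0):
        raise ValueError("group means must be positive")
    nu = n - 1.0
    v = np.array([np.sum((g - m) ** 2) for g, m in zip(groups, xbar)]) / nu
    if np.any(v == 0):
        raise ValueError("a group has zero variance")
    stat, tau_hat = _slrt_statistic(xbar, v, nu)
    stat = float(stat)
    tau_hat = float(tau_hat)
    p_asym = float(sps.chi2.sf(stat, df=k - 1))

    p_sim = None
    if n_sim and n_sim > 0:
        rng = np.random.default_rng(seed)
        mu0 = _profile_mu(xbar, v, tau_hat)
        sd0 = tau_hat * mu0
        # bootstrap via sufficient statistics: xbar ~ N(mu, sd/sqrt(n)),
        # nu*v ~ sd^2 * chi2(nu)
        xb = rng.normal(mu0, sd0 / np.sqrt(n), size=(n_sim, k))
        vv = sd0**2 * rng.chisquare(nu, size=(n_sim, k)) / nu
        stats_sim, _ = _slrt_statistic(xb, vv, nu)
        p_sim = float((1 + np.sum(stats_sim >= stat - 1e-12)) / (n_sim + 1))

    cvs = np.sqrt(v) / xbar
    return SLRTResult(
        statistic=stat,
        df=k - 1,
        p_asymptotic=p_asym,
        p_sim=p_sim,
        n_sim=int(n_sim or 0),
        cvs=cvs,
        common_cv=tau_hat,
    )
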