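"""Species-time relationships (STR): S = c * T^w.

Cumulative observed richness S grows with the length T of the observation
window; on microbial time series this is well described by the power law
``S = c * T**w`` with the exponent ``w`` measuring the temporal scaling
rate of richness (higher w, faster accumulation / higher turnover).  For
each window length T (in consecutive sampling occasions by default, or in
days) the geometric mean of cumulative richness over all contiguous
windows is taken; the power law is then fitted by nonlinear least squares
on the untransformed scale, initialized from log-log ordinary regression,
and its significance assessed by permuting the sample order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data_io import PresenceMatrix

__all__ = [
    "STRCurve",
    "STRFit",
    "cumulative_richness",
    "str_curve",
    "fit_power_law",
    "str_permutation_test",
]


@dataclass
class STRCurve:
    """Geometric-mean cumulative richness per window length."""

    T: np.ndarray       # window lengths (occasions, or binned days)
    S_geo: np.ndarray
    unit: str = "occasions"
    zero_windows: int = 0  # windows excluded for zero richness

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.S_geo = np.asarray(self.S_geo, dtype=float)


@dataclass
class STRFit:
    """Power-law fit S = c * T^w with permutation significance."""

    c_hat: float
    w_hat: float
    se_c: float
    se_w: float
    adj_R2: float
    p_perm: float | None = None
    n_perm: int = 0
    p_perm_w: float | None = None   # permutation p using w as the statistic
    converged: bool = True


def _window_richness_table(x: np.ndarray) -> np.ndarray:
    """Richness of every contiguous window, as a (start, length-1) table.

    Entry ``[a, w-1]`` is the number of taxa present at least once in
    samples ``a .. a+w-1`` (NaN where the window exceeds the series).
    Uses per-taxon next-occurrence indices so the whole table costs
    O(n_samples * n_taxa * log n_taxa).
    """
    n_taxa, n = x.shape
    nxt = np.full((n_taxa, n + 1), n, dtype=np.int64)
    cols = np.arange(n)
    for j in range(n - 1, -1, -1):
        nxt[:, j] = np.where(x[:, j], j, nxt[:, j + 1])
    out = np.full((n, n), np.nan)
    for a in range(n):
        sc = np.sort(nxt[:, a])
        ends = np.arange(a + 1, n + 1)  # window [a, end)
        out[a, : n - a] = np.searchsorted(sc, ends, side="left")
    return out


def cumulative_richness(pm: PresenceMatrix, window: int) -> np.ndarray:
    """Richness of every contiguous block of ``window`` consecutive samples.

    The value for a block is the number of taxa present in at least one of
    its samples; the result has length ``n_samples - window + 1``.
    """
    n = pm.n_samples
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, {n}]")
    x = pm.presence.astype(bool)
    out = np.empty(n - window + 1, dtype=np.int64)
    for start in range(n - window + 1):
        out[start] = x[:, start : start + window].any(axis=1).sum()
    return out


def _curve_from_table(table: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n = table.shape[0]
    T_vals, S_vals, zeros = [], [], 0
    for w in range(1, n + 1):
        rich = table[: n - w + 1, w - 1]
        pos = rich[rich > 0]
        zeros += int((rich == 0).sum())
        if len(pos):
            T_vals.append(float(w))
            S_vals.append(float(np.exp(np.mean(np.log(pos)))))
    return np.array(T_vals), np.array(S_vals), zeros


def str_curve(pm: PresenceMatrix, unit: str = "occasions", n_bins: int = 20) -> STRCurve:
    """Geometric-mean cumulative richness for every window length.

    ``unit="occasions"`` (default) uses the number of consecutive sampling
    occasions as T — robust to the irregular month grid.  ``unit="days"``
    uses each window's span in days and bins spans geometrically before
    averaging.  Windows with zero richness are excluded from the geometric
    mean (and counted in ``zero_windows``).
    """
    if pm.n_samples < 3:
        raise ValueError("need at least 3 samples for an STR curve")
    x = pm.presence.astype(bool)
    if not x.any():
        raise ValueError("all-zero presence matrix")
    table = _window_richness_table(x)
    if unit == "occasions":
        T, S, zeros = _curve_from_table(table)
        return STRCurve(T, S, unit=unit, zero_windows=zeros)
    if unit != "days":
        raise ValueError("unit must be 'occasions' or 'days'")
    n = pm.n_samples
    spans, rich_all = [], []
    zeros = 0
    for w in range(1, n + 1):
        for a in range(n - w + 1):
            r = table[a, w - 1]
            span = pm.times[a + w - 1] - pm.times[a] + 1.0
            if r > 0:
                spans.append(span)
                rich_all.append(r)
            else:
                zeros += 1
    spans = np.asarray(spans)
    rich_all = np.asarray(rich_all, dtype=float)
    edges = np.geomspace(spans.min(), spans.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(spans, edges) - 1, 0, n_bins - 1)
    T_vals, S_vals = [], []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            T_vals.append(float(np.exp(np.mean(np.log(spans[m])))))
            S_vals.append(float(np.exp(np.mean(np.log(rich_all[m])))))
    return STRCurve(np.array(T_vals), np.array(S_vals), unit="days", zero_windows=zeros)


def fit_power_law(curve: STRCurve) -> STRFit:
    """Nonlinear least squares of S_geo on c * T^w.

    Initialized from the log-log OLS estimates; standard errors from the
    Jacobian-based covariance; adjusted R^2 on the untransformed scale.
    """
    T, S = curve.T, curve.S_geo
    ok = (T > 0) & (S > 0)
    T, S = T[ok], S[ok]
    if len(np.unique(T)) < 3:
        raise ValueError("need at least 3 distinct positive (T, S) points")
    lw, lc = np.polyfit(np.log(T), np.log(S), 1)  # log-log OLS start
    p0 = (float(np.exp(lc)), float(lw))

    def model(t, c, w):
        return c * np.power(t, w)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(model, T, S, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"power-law fit failed to converge (start c={p0[0]:.4g}, w={p0[1]:.4g})"
        ) from exc
    c_hat, w_hat = float(popt[0]), float(popt[1])
    resid = S - model(T, *popt)
    n, k = len(S), 2
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((S - S.mean()) ** 2))
    if ss_tot == 0:
        adj_r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if n > k else r2
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return STRFit(
        c_hat=c_hat,
        w_hat=w_hat,
        se_c=float(se[0]),
        se_w=float(se[1]),
        adj_R2=float(np.clip(adj_r2, 0.0, 1.0)),
    )


def str_permutation_test(
    pm: PresenceMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> STRFit:
    """Permutation significance of the STR fit.

    The sample order is permuted uniformly and the full curve + fit is
    recomputed for each permutation; the p-value compares the observed
    adjusted R^2 against the permutation null with the add-one convention
    ``p = (1 + #{adj_R2_perm >= adj_R2_obs}) / (n_perm + 1)``.  A second
    p-value using ``w`` as the statistic is reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fit = fit_power_law(str_curve(pm))
    rng = np.random.default_rng(seed)
    x = pm.presence.astype(bool)
    ge_r2 = ge_w = n_eff = 0
    for _ in range(n_perm):
        perm = rng.permutation(pm.n_samples)
        T, S, _ = _curve_from_table(_window_richness_table(x[:, perm]))
        try:
            f = fit_power_law(STRCurve(T, S))
        except (ValueError, RuntimeError):
            continue
        n_eff += 1
        if f.adj_R2 >= fit.adj_R2 - 1e-12:
            ge_r2 += 1
        if f.w_hat >= fit.w_hat - 1e-12:
            ge_w += 1
    fit.n_perm = n_eff
    fit.p_perm = (1 + ge_r2) / (n_eff + 1)
    fit.p_perm_w = (1 + ge_w) / (n_eff + 1)
    return fit
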