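"""Consumer-resource + neutral stochastic model and determinism estimation.

The latent dynamics combine environmental selection and neutral noise.
Per-capita growth of taxon ``i`` follows Monod kinetics on a shared
limiting resource ``R``, filtered by a Gaussian salinity niche::

    g_i(R, s) = mu_max_i * R / (K + R) * exp(-(s - s_opt_i)^2 / (2 s_width_i^2)) - m_i

and abundances obey the SDE (Euler-Maruyama integrated)::

    dN_i = [N_i * g_i(R, s) + lambda * p_i] dt + sigma_i * sqrt(N_i) dW_i
    dR   = [D_R * (R_supply - R) - sum_i q * mu_max_i * M(R) * phi_i(s) * N_i] dt

The deterministic terms carry selection (resource competition shaped by the
salinity niche) and dispersal from a metacommunity with relative abundances
``p_i`` at rate ``lambda``; the Wiener terms carry neutral demographic
noise.  Determinism of taxon ``i`` over the sampling interval starting at
``t_k`` is the deterministic share of the expected squared increment::

    D_i(t_k) = 100 * (f_i dt_k)^2 / [(f_i dt_k)^2 + sigma_i^2 x_i dt_k]

which is 100 for noiseless dynamics and 0 for pure drift-free noise.
Community-level determinism is the mean over taxa, optionally weighted by
relative abundance.

Fitting works on relative abundances with a quasi-steady-state resource
closure and the Euler pseudo-likelihood
``dx_i(t_k) ~ Normal(f_i dt_k, sigma_i^2 x_i dt_k)``; the drift parameters
are profiled by weighted least squares per taxon and ``sigma_i`` in closed
form from the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data_io import CommunityMatrix, EnvironmentSeries

__all__ = [
    "CRNModel",
    "DeterminismResult",
    "FittedCRN",
    "drift",
    "qss_resource",
    "simulate_crn",
    "fit_crn",
    "taxon_determinism",
    "community_determinism",
]


@dataclass
class CRNModel:
    """Parameters of the consumer-resource + neutral model.

    Per-taxon arrays (length ``n_taxa``): ``mu_max`` maximal growth rate
    (1/day), ``s_opt`` salinity niche optimum (PSU), ``s_width`` niche
    width (PSU), ``m`` loss rate (1/day), ``sigma`` demographic noise
    scale (per sqrt-abundance per sqrt-day), ``p`` metacommunity relative
    abundances (sum to 1).  Shared scalars: ``K`` resource half-saturation,
    ``R_supply`` supply level, ``D_R`` resource dilution rate (1/day),
    ``lam`` immigration rate (1/day), ``q`` per-capita consumption
    coefficient.
    """

    mu_max: np.ndarray
    s_opt: np.ndarray
    s_width: np.ndarray
    m: np.ndarray
    sigma: np.ndarray
    p: np.ndarray
    K: float | np.ndarray = 1.0
    R_supply: float = 10.0
    D_R: float = 5.0
    lam: float = 1e-3
    q: float = 1.0
    noise: str = "demographic"  # sqrt(N) scaling; "environmental" scales with N

    def __post_init__(self):
        if self.noise not in ("demographic", "environmental"):
            raise ValueError("noise must be 'demographic' or 'environmental'")
        arrs = {}
        n = None
        for name in ("mu_max", "s_opt", "s_width", "m", "sigma", "p"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            arrs[name] = v
            n = len(v) if n is None else max(n, len(v))
        for name, v in arrs.items():
            if len(v) == 1 and n > 1:
                v = np.repeat(v, n)
            if len(v) != n:
                raise ValueError(f"parameter {name} has inconsistent length")
            setattr(self, name, v)
        if np.any(self.s_width <= 0):
            raise ValueError("s_width must be positive")
        for name in ("mu_max", "m", "sigma"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(self.p < 0) or self.p.sum() <= 0:
            raise ValueError("p must be a non-negative vector with positive sum")
        self.p = self.p / self.p.sum()
        if np.ndim(self.K) > 0:  # per-taxon half-saturation is allowed
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != self.mu_max.shape:
                raise ValueError("per-taxon K must match the number of taxa")
            if np.any(self.K < 0):
                raise ValueError("K must be non-negative")
        elif self.K < 0:
            raise ValueError("K must be non-negative")
        if min(self.R_supply, self.D_R, self.lam, self.q) < 0:
            raise ValueError("shared parameters must be non-negative")

    @property
    def n_taxa(self) -> int:
        return len(self.mu_max)

    def niche(self, s: float) -> np.ndarray:
        """Gaussian salinity filter phi_i(s) in (0, 1]."""
        return np.exp(-((s - self.s_opt) ** 2) / (2.0 * self.s_width**2))


def drift(model: CRNModel, N: np.ndarray, R: float, s: float):
    """Deterministic rates of change ``(f, f_R)`` at state (N, R, salinity s)."""
    N = np.asarray(N, dtype=float)
    monod = R / (model.K + R) if R > 0 else 0.0
    phi = model.niche(s)
    growth = model.mu_max * monod * phi
    f = N * (growth - model.m) + model.lam * model.p
    f_R = model.D_R * (model.R_supply - R) - model.q * float(np.sum(growth * N))
    return f, f_R


def qss_resource(model: CRNModel, N: np.ndarray, s: float) -> float:
    """Quasi-steady-state resource level: the root of ``f_R = 0`` in [0, R_supply].

    With a shared Monod half-saturation the balance
    ``D_R (R_supply - R) = C R / (K + R)`` (with ``C = q * sum mu_max_i
    phi_i N_i``) is quadratic in R and has a single closed-form root in the
    feasible range; with per-taxon K the root is bracketed numerically.
    """
    if np.ndim(model.K) > 0:
        def f_R(R):
            return drift(model, N, R, s)[1]

        if f_R(model.R_supply) >= 0:
            return model.R_supply
        return float(optimize.brentq(f_R, 0.0, model.R_supply, xtol=1e-12))
    C = model.q * float(np.sum(model.mu_max * model.niche(s) * np.asarray(N, dtype=float)))
    return _qss_root(model.D_R, model.R_supply, model.K, C)


def _qss_root(D_R: float, R_supply: float, K: float, C: float) -> float:
    if D_R <= 0:
        return R_supply
    b = D_R * (R_supply - K) - C
    return float((b + np.sqrt(b * b + 4.0 * D_R * D_R * R_supply * K)) / (2.0 * D_R))


def simulate_crn(
    model: CRNModel,
    times: np.ndarray,
    env: EnvironmentSeries | np.ndarray | None,
    dt_int: float = 0.25,
    seed: int = 0,
    N0: np.ndarray | None = None,
    R0: float | None = None,
    burn_in: float = 365.0,
):
    """Euler-Maruyama integration of the SDE, reported at ``times``.

    ``env`` supplies salinity at the sample times (linearly interpolated
    between them for sub-steps); pass ``None`` for a constant salinity
    equal to the mean niche optimum.  Before the first sample the system
    is relaxed for ``burn_in`` days at the first sample's salinity so the
    recorded series starts near its stationary regime rather than in a
    colonization transient; ``N0`` (default: metacommunity proportions
    scaled to a total of 1000) sets the pre-burn-in state.  Negative
    abundance excursions are clipped to zero.  Returns ``(N_traj,
    R_traj)`` with ``N_traj`` of shape ``(n_taxa, len(times))``.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if dt_int <= 0 or dt_int > np.diff(times).min():
        raise ValueError("dt_int must be positive and <= the smallest interval")
    if env is None:
        sal = np.full_like(times, float(np.mean(model.s_opt)))
    elif isinstance(env, EnvironmentSeries):
        sal = env.salinity
    else:
        sal = np.asarray(env, dtype=float)
    if sal.shape != times.shape:
        raise ValueError("salinity must be given at every sample time")

    rng = np.random.default_rng(seed)
    N = (model.p * 1000.0 if N0 is None else np.asarray(N0, dtype=float)).copy()
    R = qss_resource(model, N, sal[0]) if R0 is None else float(R0)

    K_bar = float(np.mean(model.K))

    def step(N, R, s, h):
        # abundances: Euler-Maruyama; resource: exponential relaxation to its
        # quasi-steady state (the resource equation is stiff when uptake is fast)
        f, _ = drift(model, N, R, s)
        Npos = np.maximum(N, 0.0)
        scale = np.sqrt(Npos * h) if model.noise == "demographic" else Npos * np.sqrt(h)
        N = N + f * h + model.sigma * scale * rng.standard_normal(model.n_taxa)
        np.clip(N, 0.0, None, out=N)
        R_star = qss_resource(model, N, s)
        C = model.q * float(np.sum(model.mu_max * model.niche(s) * N))
        lam_R = model.D_R + C * K_bar / (K_bar + R_star) ** 2
        R = R_star + (R - R_star) * np.exp(-lam_R * h) if lam_R > 0 else R
        return N, float(R)

    if burn_in > 0:
        n_burn = int(np.ceil(burn_in / dt_int))
        h = burn_in / n_burn
        for _ in range(n_burn):
            N, R = step(N, R, sal[0], h)
    n_out = len(times)
    N_traj = np.empty((model.n_taxa, n_out))
    R_traj = np.empty(n_out)
    N_traj[:, 0], R_traj[0] = N, R

    for k in range(n_out - 1):
        span = times[k + 1] - times[k]
        n_sub = max(1, int(np.ceil(span / dt_int)))
        h = span / n_sub
        for j in range(n_sub):
            frac = (j * h) / span
            s = sal[k] * (1 - frac) + sal[k + 1] * frac
            N, R = step(N, R, s, h)
            if not (np.all(np.isfinite(N)) and np.isfinite(R)):
                raise FloatingPointError(
                    f"non-finite state at t={times[k] + (j + 1) * h:.2f} "
                    f"(interval {k}, sub-step {j})"
                )
        N_traj[:, k + 1], R_traj[k + 1] = N, R
    return N_traj, R_traj


# ---------------------------------------------------------------------------
# Fitting (Euler pseudo-likelihood on relative abundances)
# ---------------------------------------------------------------------------

_X_FLOOR = 1e-6  # variance floor for absent taxa in the pseudo-likelihood


@dataclass
class FittedCRN:
    """Per-taxon fitted parameters plus the drift/noise decomposition."""

    taxon_ids: list[str]
    mu_max: np.ndarray
    s_opt: np.ndarray
    s_width: np.ndarray
    m: np.ndarray
    sigma: np.ndarray
    K: float
    lam: float
    p: np.ndarray
    x: np.ndarray              # relative abundances, taxa x times
    f: np.ndarray              # fitted drift, taxa x (times - 1) intervals
    dt: np.ndarray             # interval lengths, days
    times: np.ndarray
    fitted_mask: np.ndarray    # False where the taxon was skipped
    skipped: list[str] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


def _taxon_objective(theta, y_adj, wt, z_s, monod):
    # weighted squared error of per-capita growth; wt = N*dt (delta-method
    # precision of the log-increment under demographic noise)
    mu_max, s_opt, s_width, m = theta
    phi = np.exp(-((z_s - s_opt) ** 2) / (2.0 * s_width**2))
    g = mu_max * monod * phi - m
    return float(np.sum(wt * (y_adj - g) ** 2))


def fit_crn(
    cm: CommunityMatrix | np.ndarray,
    env: EnvironmentSeries | np.ndarray,
    top_k: int = 50,
    times: np.ndarray | None = None,
    K: float = 1.0,
    R_supply: float = 10.0,
    D_R: float = 5.0,
    q: float = 1.0,
    lam: float = 0.0,
    mu_ref: float = 1.0,
    n_passes: int = 3,
    frame: str = "relative",
    resource: np.ndarray | None = None,
    taxon_ids: list[str] | None = None,
) -> FittedCRN:
    """Fit per-taxon niche/growth/noise parameters to a community series.

    Counts are converted to relative abundances; only the ``top_k`` most
    abundant taxa are fitted (the remainder is excluded from community
    aggregates rather than merged).  Because relative abundances sum to
    one, their deterministic increments follow the replicator form
    ``dx_i = x_i (g_i - gbar) dt`` with ``gbar`` the abundance-weighted
    mean per-capita growth; ``gbar`` is re-estimated over ``n_passes``
    alternating passes from the per-taxon growth curves, which keeps the
    pseudo-likelihood separable per taxon.  The resource is closed at
    quasi-steady state against aggregate community consumption with a
    reference uptake (``mu_ref``, flat niche); ``K``, ``q`` and the
    immigration rate ``lam`` are shared and fixed.  Per taxon, the
    pseudo-likelihood is Gaussian on the per-capita log increments,
    ``dlog x_i(t_k) ~ Normal(g_i dt_k, sigma_i^2 dt_k / x_i)`` — the
    first-order (Euler) increment model expressed per capita, which stays
    well behaved when ``g dt`` is order one over month-long intervals.
    Niche shape is found on a coarse (optimum, width) grid with
    ``(mu_max, m)`` profiled by non-negative least squares, then polished
    by bounded quasi-Newton; ``sigma`` follows in closed form from the
    weighted residuals.  Taxa with fewer than 3 nonzero observations are
    skipped and flagged.

    ``frame`` selects the data frame: ``"relative"`` (default; counts or
    compositions, replicator drift with the ``gbar`` offset) or
    ``"absolute"`` (latent abundance trajectories; per-taxon drift
    ``dN_i = N_i g_i dt``, no common-mode offset).  Niche optima are fully
    identifiable only in the absolute frame: compositional data determine
    per-capita growth only up to a shared time-varying common mode.

    If the limiting resource was measured, pass its per-sample levels as
    ``resource``; the Monod factor is then computed from data instead of
    the quasi-steady-state closure, which removes the shared-resource
    common mode and makes niche parameters cleanly identifiable.
    """
    if isinstance(cm, CommunityMatrix):
        if times is not None:
            raise ValueError("times is inferred from the CommunityMatrix")
        if len(cm.stations) > 1:
            raise ValueError("fit_crn expects a single station; subset first")
        x_all = cm.relative_abundance()
        times = cm.times
        ids_all = cm.taxon_ids
        sal = env.align(cm.sample_ids).salinity if isinstance(env, EnvironmentSeries) else np.asarray(env, float)
    else:
        x_all = np.asarray(cm, dtype=float)
        if times is None:
            raise ValueError("times required when passing a bare abundance matrix")
        times = np.asarray(times, dtype=float)
        ids_all = taxon_ids if taxon_ids is not None else [f"t{i}" for i in range(x_all.shape[0])]
        sal = env.salinity if isinstance(env, EnvironmentSeries) else np.asarray(env, float)
    if x_all.shape[1] < 10:
        raise ValueError("need at least 10 time points to fit the process model")

    order = np.argsort(-x_all.mean(axis=1), kind="stable")[: min(top_k, x_all.shape[0])]
    x = x_all[order]
    ids = [ids_all[i] for i in order]
    n_taxa, n_t = x.shape
    dt = np.diff(times)
    x_start = x[:, :-1]
    # per-capita growth observations: log increments with a small floor so
    # absences stay finite (their weight is correspondingly tiny)
    y_pc = np.log((x[:, 1:] + _X_FLOOR) / (x_start + _X_FLOOR)) / dt
    wt_all = (x_start + _X_FLOOR) * dt  # inverse variance of y_pc, / sigma^2

    # initial resource closure: quasi-steady state under a unit reference
    # consumer with a flat niche; refined per pass in the absolute frame
    if resource is not None:
        resource = np.asarray(resource, dtype=float)
        if resource.shape != times.shape:
            raise ValueError("resource must be given at every sample time")
        R_mid = 0.5 * (resource[:-1] + resource[1:])
        monod = R_mid / (K + R_mid)
    else:
        R_hat = _qss_root(D_R, R_supply, K, q * mu_ref)
        monod = R_hat / (K + R_hat)

    s_lo, s_hi = float(np.min(sal)), float(np.max(sal))
    s_pad = max(1.0, 0.5 * (s_hi - s_lo))
    bounds = [
        (0.0, 10.0),                       # mu_max (1/day)
        (s_lo - s_pad, s_hi + s_pad),      # s_opt (PSU)
        (2.0, 100.0),                      # s_width (PSU)
        (0.0, 10.0),                       # m (1/day)
    ]
    # niche-shape grid for the profiled search; (mu_max, m) are linear given
    # the shape and solved by non-negative least squares at each grid node
    sopt_grid = (
        np.linspace(s_lo - s_pad, s_hi + s_pad, 21) if s_hi > s_lo else np.array([s_lo])
    )
    # minimum width 2 PSU: narrower niches are below the sample-to-sample
    # salinity variation and only chase noise
    swidth_grid = np.array([2.0, 4.0, 6.0, 9.0, 14.0, 25.0, 60.0])

    mu_fit = np.zeros(n_taxa)
    sopt_fit = np.full(n_taxa, np.mean(sal))
    swid_fit = np.full(n_taxa, 10.0)
    m_fit = np.zeros(n_taxa)
    sig_fit = np.zeros(n_taxa)
    f_fit = np.zeros((n_taxa, n_t - 1))
    fitted = np.zeros(n_taxa, dtype=bool)
    skipped: list[str] = []
    p_meta = np.maximum(x.mean(axis=1), 1e-12)
    p_meta = p_meta / p_meta.sum()
    # niche evaluated at the interval-midpoint salinity: the increment over a
    # month-long interval reflects the salinity path, not its start value
    sal_mid = 0.5 * (sal[:-1] + sal[1:])

    def growth(i):
        phi = np.exp(-((sal_mid - sopt_fit[i]) ** 2) / (2.0 * swid_fit[i] ** 2))
        return mu_fit[i] * monod * phi - m_fit[i]

    if frame not in ("relative", "absolute"):
        raise ValueError("frame must be 'relative' or 'absolute'")
    monod = np.broadcast_to(np.asarray(monod, dtype=float), (n_t - 1,)).copy()
    gbar = np.zeros(n_t - 1)
    for _pass in range(n_passes):
        for i in range(n_taxa):
            if np.count_nonzero(x[i]) < 3:
                if _pass == 0:
                    skipped.append(ids[i])
                continue
            # observed per-capita growth (log increments), delta-method weights
            y_adj = y_pc[i] + gbar
            wt = wt_all[i]
            args = (y_adj, wt, sal_mid, monod)
            sw = np.sqrt(wt)
            b = sw * y_adj
            col_m = -sw * np.ones(n_t - 1)
            best_grid = None
            for s0 in sopt_grid:
                for w0 in swidth_grid:
                    phi = np.exp(-((sal_mid - s0) ** 2) / (2.0 * w0**2))
                    A = np.column_stack([sw * monod * phi, col_m])
                    coef, rss = optimize.nnls(A, b)
                    if best_grid is None or rss < best_grid[0]:
                        best_grid = (rss, coef[0], s0, w0, coef[1])
            x0_opt = np.clip(
                np.array(best_grid[1:]),
                [bb[0] for bb in bounds],
                [bb[1] for bb in bounds],
            )
            res = optimize.minimize(
                _taxon_objective, x0_opt, args=args, method="L-BFGS-B", bounds=bounds
            )
            rss_niche, theta = min(
                [(res.fun, res.x), (best_grid[0] ** 2, x0_opt)], key=lambda t: t[0]
            )
            # parsimony: a flat (no-niche) 2-parameter model competes by BIC,
            # so noise alone does not earn a salinity response
            A_flat = np.column_stack([sw * monod, col_m])
            coef_flat, rss_flat = optimize.nnls(A_flat, b)
            n_int = n_t - 1
            bic_niche = n_int * np.log(max(rss_niche, 1e-300) / n_int) + 4 * np.log(n_int)
            bic_flat = n_int * np.log(max(rss_flat**2, 1e-300) / n_int) + 2 * np.log(n_int)
            if bic_flat <= bic_niche:
                theta = np.array([coef_flat[0], np.mean(sal), 1e6, coef_flat[1]])
            mu_fit[i], sopt_fit[i], swid_fit[i], m_fit[i] = theta
            fitted[i] = True
        if frame == "relative":
            # abundance-weighted mean growth over the fitted taxa (replicator offset)
            g_all = np.stack([growth(i) if fitted[i] else np.zeros(n_t - 1) for i in range(n_taxa)])
            wts = np.where(fitted[:, None], x_start, 0.0)
            denom = np.maximum(wts.sum(axis=0), 1e-12)
            gbar = (wts * g_all).sum(axis=0) / denom
        elif resource is None:
            # absolute abundances: refresh the quasi-steady-state resource from
            # the fitted uptake (community consumption shapes realized growth)
            phi_all = np.stack(
                [
                    np.exp(-((sal_mid - sopt_fit[i]) ** 2) / (2.0 * swid_fit[i] ** 2))
                    if fitted[i]
                    else np.zeros(n_t - 1)
                    for i in range(n_taxa)
                ]
            )
            C = q * (mu_fit[:, None] * phi_all * x_start).sum(axis=0)
            R_hat_t = np.array([_qss_root(D_R, R_supply, K, c) for c in C])
            monod = R_hat_t / (K + R_hat_t)

    for i in range(n_taxa):
        if not fitted[i]:
            continue
        f_fit[i] = x_start[i] * (growth(i) - gbar) + lam * p_meta[i]
        # dof-corrected residual variance (4 drift parameters per taxon)
        n_int = n_t - 1
        sig_fit[i] = float(
            np.sqrt(
                np.sum(wt_all[i] * (y_pc[i] - (growth(i) - gbar)) ** 2)
                / max(n_int - 4, 1)
            )
        )

    return FittedCRN(
        taxon_ids=ids,
        mu_max=mu_fit,
        s_opt=sopt_fit,
        s_width=swid_fit,
        m=m_fit,
        sigma=sig_fit,
        K=K,
        lam=lam,
        p=p_meta,
        x=x,
        f=f_fit,
        dt=dt,
        times=times,
        fitted_mask=fitted,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------


@dataclass
class DeterminismResult:
    """Per-taxon, per-time determinism (0-100) and community aggregates."""

    D: np.ndarray               # taxa x times, percent
    D_unweighted: np.ndarray    # per time
    D_weighted: np.ndarray      # per time
    D_mean_unweighted: float
    D_mean_weighted: float
    taxon_ids: list[str]
    times: np.ndarray
    flagged_times: list[int] = field(default_factory=list)


def taxon_determinism(f: float, sigma: float, x: float, dt: float) -> float:
    """Deterministic share (percent) of the expected squared increment."""
    num = (f * dt) ** 2
    den = num + sigma**2 * max(x, 0.0) * dt
    if den == 0.0:
        return 0.0
    return 100.0 * num / den


def determinism_matrix(fit: FittedCRN) -> np.ndarray:
    """Taxa x intervals matrix of determinism percentages from a fit."""
    num = (fit.f * fit.dt) ** 2
    den = num + (fit.sigma[:, None] ** 2) * np.maximum(fit.x[:, :-1], 0.0) * fit.dt
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(den > 0, 100.0 * num / den, 0.0)
    D[~fit.fitted_mask] = np.nan
    return D


def community_determinism(
    D: np.ndarray,
    abundances: np.ndarray,
    taxon_ids: list[str] | None = None,
    times: np.ndarray | None = None,
) -> DeterminismResult:
    """Aggregate per-taxon determinism to the community level.

    ``D`` and ``abundances`` share axes (taxa x times).  At each time the
    unweighted aggregate averages over taxa present (positive abundance,
    finite D); the weighted aggregate weights by relative abundance.
    Times with an empty community are omitted and flagged.
    """
    D = np.asarray(D, dtype=float)
    x = np.asarray(abundances, dtype=float)
    if D.shape != x.shape:
        raise ValueError("D and abundances must share axes")
    n_taxa, n_t = D.shape
    unw = np.full(n_t, np.nan)
    wgt = np.full(n_t, np.nan)
    flagged = []
    for k in range(n_t):
        mask = (x[:, k] > 0) & np.isfinite(D[:, k])
        if not mask.any():
            flagged.append(k)
            continue
        unw[k] = D[mask, k].mean()
        wgt[k] = np.average(D[mask, k], weights=x[mask, k])
    ok = np.isfinite(unw)
    return DeterminismResult(
        D=D,
        D_unweighted=unw,
        D_weighted=wgt,
        D_mean_unweighted=float(unw[ok].mean()) if ok.any() else np.nan,
        D_mean_weighted=float(wgt[ok].mean()) if ok.any() else np.nan,
        taxon_ids=taxon_ids if taxon_ids is not None else [f"t{i}" for i in range(n_taxa)],
        times=np.asarray(times, float) if times is not None else np.arange(n_t, dtype=float),
        flagged_times=flagged,
    )


def determinism_from_fit(fit: FittedCRN) -> DeterminismResult:
    """Convenience: determinism matrix + community aggregates from a fit."""
    D = determinism_matrix(fit)
    return community_determinism(
        D, fit.x[:, :-1], taxon_ids=fit.taxon_ids, times=fit.times[:-1]
    )
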