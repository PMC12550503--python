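"""Dual-step imputation: correlation-weighted CTWH estimate merged with a
multitask Gaussian-process posterior on a regular hourly grid.

The GP is a standard dense multitask model in standardized (z-score)
space.  Its covariance between observation (t, variable i) and
(s, variable j) is an intrinsic-coregionalization sum

    K = c · B[i, j] · k(|t−s|; ℓ_shared)  +  δ_ij · s² · k(|t−s|; ℓ_i)
        + δ_ij δ_ts · σ_n²

where ``B`` is a low-rank, unit-diagonal cross-variable correlation
matrix estimated from episode-level variable means, the shared kernel
carries cross-variable coupling, and the independent kernel carries each
variable's own temporal structure with its length scale ℓ_i initialized
to the variable's CTWH window size (the stage's own estimate of temporal
coherence).  The default time kernel is exponential (Ornstein–Uhlenbeck)
— physiologic signals are rough; a squared-exponential is available.

Only observations within each variable's CTWH span of the prediction
cutoff condition the posterior; grid cells beyond the span are filled
with the population median and flagged rather than extrapolated.

The final grid value is a convex combination of the GP posterior mean
and the correlation-weighted window estimate,
``λ·ctwh + (1−λ)·mgp`` with λ = (fraction of non-empty windows) ×
``fixed_weight`` in correlation mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize

from .ctwh import WindowConfig, window_means
from .ehr import Episode
from .panel import FeaturePanel

OBSERVED = "observed"
MGP = "mgp"
CTWH_MERGE = "ctwh_merge"
OUT_OF_SPAN = "out_of_span"


class ImputationError(RuntimeError):
    """Raised when the GP covariance cannot be factorized."""


@dataclass
class MgpConfig:
    kernel: str = "exponential"  # or "squared_exponential"
    task_rank: int = 5
    noise_floor: float = 1e-4
    jitter: float = 1e-6
    max_opt_iter: int = 30
    optimize: bool = True
    n_fit_episodes: int = 8
    merge_weight_mode: str = "correlation"  # or "fixed"
    fixed_weight: float = 0.5
    observed_tolerance_h: float = 0.5

    def __post_init__(self) -> None:
        if self.kernel not in ("exponential", "squared_exponential"):
            raise ValueError("kernel must be exponential or squared_exponential")
        if self.jitter <= 0:
            raise ValueError("jitter must be > 0")
        if not 0.0 <= self.fixed_weight <= 1.0:
            raise ValueError("fixed_weight must lie in [0, 1]")


@dataclass
class MgpHyperparameters:
    """Population-level hyperparameters shared by all episode posteriors."""

    variables: list[str]
    means: np.ndarray          # raw-space prior mean per variable
    scales: np.ndarray         # raw-space sd per variable (>0)
    medians: np.ndarray        # raw-space fallback value per variable
    length_scales_h: np.ndarray
    shared_length_scale_h: float
    task_corr: np.ndarray      # V×V, unit diagonal, PSD
    coupling_var: float = 0.5  # c
    indep_var: float = 0.5     # s²
    noise_var: float = 0.01    # σ_n², standardized space

    def index(self, variable: str) -> int:
        return self.variables.index(variable)


def _time_kernel(d: np.ndarray, ell: np.ndarray | float, kind: str) -> np.ndarray:
    if kind == "exponential":
        return np.exp(-d / ell)
    return np.exp(-0.5 * (d / ell) ** 2)


def _cov(
    t1: np.ndarray, task1: np.ndarray,
    t2: np.ndarray, task2: np.ndarray,
    hp: MgpHyperparameters, cfg: MgpConfig,
) -> np.ndarray:
    """Cross-covariance (no noise) between two (time, task) point sets."""
    d = np.abs(t1[:, None] - t2[None, :])
    shared = hp.coupling_var * hp.task_corr[task1[:, None], task2[None, :]]
    k = shared * _time_kernel(d, hp.shared_length_scale_h, cfg.kernel)
    same = task1[:, None] == task2[None, :]
    if same.any():
        ell_i = hp.length_scales_h[task1][:, None]
        k_ind = hp.indep_var * _time_kernel(d, ell_i, cfg.kernel)
        k = k + np.where(same, k_ind, 0.0)
    return k


def estimate_task_correlation(
    episodes: list[Episode], variables: list[str], rank: int
) -> np.ndarray:
    """Low-rank cross-variable correlation from per-episode variable means.

    Pairwise-complete Pearson correlations, truncated to the leading
    ``rank`` eigencomponents, ridged and renormalized to unit diagonal.
    """
    v = len(variables)
    m = np.full((len(episodes), v), np.nan)
    for i, ep in enumerate(episodes):
        for j, code in enumerate(variables):
            _, vals = ep.times_values(code)
            if len(vals):
                m[i, j] = float(np.mean(vals))
    df_corr = np.eye(v)
    for a in range(v):
        for b in range(a + 1, v):
            ok = ~np.isnan(m[:, a]) & ~np.isnan(m[:, b])
            if ok.sum() >= 3 and m[ok, a].std() > 0 and m[ok, b].std() > 0:
                df_corr[a, b] = df_corr[b, a] = float(np.corrcoef(m[ok, a], m[ok, b])[0, 1])
    w, u = np.linalg.eigh(df_corr)
    keep = np.argsort(w)[::-1][: max(1, min(rank, v))]
    low = (u[:, keep] * np.clip(w[keep], 0.0, None)) @ u[:, keep].T
    low += 0.05 * np.eye(v)
    dsq = np.sqrt(np.clip(np.diag(low), 1e-12, None))
    return low / np.outer(dsq, dsq)


def _episode_points(
    episode: Episode,
    hp: MgpHyperparameters,
    windows: WindowConfig,
    cutoff_h: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, task indices, standardized values) of the observations
    that may condition the posterior: at or before the cutoff and within
    each variable's CTWH span of it."""
    ts, tasks, ys = [], [], []
    for j, code in enumerate(hp.variables):
        if code not in windows:
            continue
        span = windows.span_h(code)
        t, v = episode.times_values(code)
        mask = (t <= cutoff_h) & (t >= cutoff_h - span)
        for tt, vv in zip(t[mask], v[mask]):
            ts.append(tt)
            tasks.append(j)
            ys.append((vv - hp.means[j]) / hp.scales[j])
    return (
        np.asarray(ts, dtype=float),
        np.asarray(tasks, dtype=int),
        np.asarray(ys, dtype=float),
    )


@dataclass
class MgpPosterior:
    """Fitted per-episode posterior state (standardized space)."""

    episode_id: str
    hp: MgpHyperparameters
    cfg: MgpConfig
    cutoff_h: float
    t_train: np.ndarray
    task_train: np.ndarray
    chol: np.ndarray | None
    alpha: np.ndarray | None  # K^{-1} y
    fallback: bool = False

    def predict(self, times: np.ndarray, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and sd for one variable, raw units."""
        j = self.hp.index(variable)
        times = np.asarray(times, dtype=float)
        tasks = np.full(len(times), j, dtype=int)
        prior_var = self.hp.coupling_var + self.hp.indep_var
        if self.fallback or self.chol is None or len(self.t_train) == 0:
            mean_z = np.zeros(len(times))
            var_z = np.full(len(times), prior_var)
        else:
            k_star = _cov(times, tasks, self.t_train, self.task_train, self.hp, self.cfg)
            mean_z = k_star @ self.alpha
            w = solve_triangular(self.chol, k_star.T, lower=True)
            var_z = prior_var - np.einsum("ij,ij->j", w, w)
            var_z = np.clip(var_z, 0.0, None)
        mean = self.hp.means[j] + self.hp.scales[j] * mean_z
        sd = self.hp.scales[j] * np.sqrt(var_z)
        return mean, sd


def _chol_with_jitter(k: np.ndarray, jitter: float, episode_id: str) -> np.ndarray:
    j = jitter
    while j <= 1e-2:
        try:
            return np.linalg.cholesky(k + j * np.eye(len(k)))
        except np.linalg.LinAlgError:
            j *= 10.0
    raise ImputationError(f"covariance singular after jitter escalation (episode {episode_id})")


def fit_mgp(
    episode: Episode,
    panel: FeaturePanel,
    windows: WindowConfig,
    cfg: MgpConfig | None = None,
    hypers: MgpHyperparameters | None = None,
    cutoff_h: float | None = None,
) -> MgpPosterior:
    """Condition the multitask GP on one episode's in-span observations.

    ``hypers`` normally come from :func:`fit_hyperparameters` (population
    level); when omitted, neutral defaults over the window config's
    variables are used. ``cutoff_h`` defaults to the episode reference
    time; observations after it never condition the posterior.
    """
    cfg = cfg or MgpConfig()
    if hypers is None:
        hypers = default_hyperparameters(panel, windows)
    cutoff = episode.reference_time_h if cutoff_h is None else cutoff_h
    t, task, y = _episode_points(episode, hypers, windows, cutoff)
    if len(t) == 0:
        return MgpPosterior(
            episode.episode_id, hypers, cfg, cutoff,
            t, task, None, None, fallback=True,
        )
    k = _cov(t, task, t, task, hypers, cfg)
    k[np.diag_indices_from(k)] += max(hypers.noise_var, cfg.noise_floor)
    chol = _chol_with_jitter(k, cfg.jitter, episode.episode_id)
    alpha = cho_solve((chol, True), y)
    return MgpPosterior(episode.episode_id, hypers, cfg, cutoff, t, task, chol, alpha)


def default_hyperparameters(
    panel: FeaturePanel,
    windows: WindowConfig,
    means: dict[str, float] | None = None,
    scales: dict[str, float] | None = None,
) -> MgpHyperparameters:
    """Neutral hyperparameters: unit task correlation off-diagonal zero,
    length scales from the window config, z-scoring from panel midpoints
    when no population statistics are supplied."""
    variables = [c for c in panel.dynamic_codes if c in windows]
    v = len(variables)
    mean_arr = np.zeros(v)
    scale_arr = np.ones(v)
    for j, code in enumerate(variables):
        spec = panel[code]
        mean_arr[j] = means.get(code) if means else (spec.plausible_low + spec.plausible_high) / 2
        scale_arr[j] = scales.get(code) if scales else (spec.plausible_high - spec.plausible_low) / 4
    ls = np.array([max(windows.window_size_h(c), 0.25) for c in variables])
    return MgpHyperparameters(
        variables=variables,
        means=mean_arr,
        scales=np.clip(scale_arr, 1e-6, None),
        medians=mean_arr.copy(),
        length_scales_h=ls,
        shared_length_scale_h=float(np.median(ls)),
        task_corr=np.eye(v),
    )


def _neg_log_marginal(
    theta: np.ndarray,
    point_sets: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    hp: MgpHyperparameters,
    cfg: MgpConfig,
) -> float:
    c, s2, noise = np.exp(theta)
    trial = MgpHyperparameters(
        variables=hp.variables, means=hp.means, scales=hp.scales, medians=hp.medians,
        length_scales_h=hp.length_scales_h,
        shared_length_scale_h=hp.shared_length_scale_h,
        task_corr=hp.task_corr,
        coupling_var=float(c), indep_var=float(s2),
        noise_var=float(max(noise, cfg.noise_floor)),
    )
    total = 0.0
    for t, task, y in point_sets:
        k = _cov(t, task, t, task, trial, cfg)
        k[np.diag_indices_from(k)] += trial.noise_var
        try:
            chol = np.linalg.cholesky(k + cfg.jitter * np.eye(len(k)))
        except np.linalg.LinAlgError:
            return 1e10
        alpha = cho_solve((chol, True), y)
        total += 0.5 * float(y @ alpha) + float(np.log(np.diag(chol)).sum())
        total += 0.5 * len(y) * math.log(2.0 * math.pi)
    return total


def fit_hyperparameters(
    episodes: list[Episode],
    panel: FeaturePanel,
    windows: WindowConfig,
    cfg: MgpConfig | None = None,
    seed: int = 0,
) -> MgpHyperparameters:
    """Population-level hyperparameters by marginal-likelihood maximization.

    Standardization statistics and the low-rank task correlation come
    from the whole cohort; the three scalar magnitudes (coupling
    variance, independent variance, noise variance) are optimized by
    L-BFGS on the summed log marginal likelihood of a seeded episode
    subsample. Length scales stay tied to the CTWH window sizes.
    """
    cfg = cfg or MgpConfig()
    variables = [c for c in panel.dynamic_codes if c in windows]
    v = len(variables)
    means = np.zeros(v)
    scales = np.ones(v)
    medians = np.zeros(v)
    for j, code in enumerate(variables):
        vals = np.concatenate([ep.times_values(code)[1] for ep in episodes]) if episodes else np.empty(0)
        if len(vals) >= 2:
            means[j] = float(np.mean(vals))
            scales[j] = float(max(np.std(vals), 1e-6))
            medians[j] = float(np.median(vals))
        else:
            spec = panel[code]
            means[j] = (spec.plausible_low + spec.plausible_high) / 2
            scales[j] = (spec.plausible_high - spec.plausible_low) / 4
            medians[j] = means[j]
    ls = np.array([max(windows.window_size_h(c), 0.25) for c in variables])
    hp = MgpHyperparameters(
        variables=variables, means=means, scales=scales, medians=medians,
        length_scales_h=ls,
        shared_length_scale_h=float(np.median(ls)),
        task_corr=estimate_task_correlation(episodes, variables, cfg.task_rank),
    )
    if not cfg.optimize:
        return hp
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(episodes))[: cfg.n_fit_episodes]
    point_sets = []
    for i in idx:
        ep = episodes[int(i)]
        pts = _episode_points(ep, hp, windows, ep.reference_time_h)
        if len(pts[0]) >= 3:
            point_sets.append(pts)
    if not point_sets:
        return hp
    res = minimize(
        _neg_log_marginal,
        x0=np.log([hp.coupling_var, hp.indep_var, hp.noise_var]),
        args=(point_sets, hp, cfg),
        method="L-BFGS-B",
        bounds=[(-6, 3), (-6, 3), (-9, 0)],
        options={"maxiter": cfg.max_opt_iter},
    )
    c, s2, noise = np.exp(res.x)
    hp.coupling_var = float(c)
    hp.indep_var = float(s2)
    hp.noise_var = float(max(noise, cfg.noise_floor))
    return hp


@dataclass
class ImputedGrid:
    """Regular hourly value + uncertainty lattice for one episode."""

    episode_id: str
    cutoff_h: float
    grid_times_h: np.ndarray
    variables: list[str]
    values: np.ndarray  # V × T
    sd: np.ndarray      # V × T
    source: np.ndarray  # V × T of flag strings
    fallback: bool = False

    def row(self, variable: str) -> int:
        return self.variables.index(variable)

    def series(self, variable: str) -> np.ndarray:
        return self.values[self.row(variable)]


def impute_grid(posterior: MgpPosterior, grid_times: np.ndarray, windows: WindowConfig) -> ImputedGrid:
    """Pure-GP grid: posterior means and sds, span and fallback flags.

    Raises when any grid time lies after the posterior cutoff — the
    imputation must never peek forward.
    """
    grid_times = np.asarray(grid_times, dtype=float)
    if np.any(grid_times > posterior.cutoff_h + 1e-9):
        raise ValueError("grid extends beyond the posterior cutoff")
    hp = posterior.hp
    v, t = len(hp.variables), len(grid_times)
    values = np.empty((v, t))
    sd = np.empty((v, t))
    source = np.full((v, t), MGP, dtype=object)
    for j, code in enumerate(hp.variables):
        mean_j, sd_j = posterior.predict(grid_times, code)
        values[j], sd[j] = mean_j, sd_j
        span = windows.span_h(code) if code in windows else np.inf
        out = grid_times < posterior.cutoff_h - span
        values[j, out] = hp.medians[j]
        sd[j, out] = hp.scales[j] * math.sqrt(hp.coupling_var + hp.indep_var)
        source[j, out] = OUT_OF_SPAN
        if posterior.fallback:
            values[j, ~out] = hp.medians[j]
            source[j, ~out] = OUT_OF_SPAN
        else:
            near = np.min(
                np.abs(grid_times[:, None] - posterior.t_train[posterior.task_train == j][None, :]),
                axis=1, initial=np.inf,
            )
            source[j, (~out) & (near <= posterior.cfg.observed_tolerance_h)] = OBSERVED
    return ImputedGrid(
        posterior.episode_id, posterior.cutoff_h, grid_times,
        list(hp.variables), values, sd, source, fallback=posterior.fallback,
    )


def ctwh_estimate(
    episode: Episode,
    variable: str,
    windows: WindowConfig,
    t: float,
) -> tuple[float, float]:
    """Correlation-weighted window estimate at time ``t``.

    The N referenced windows end at ``t``; weights are the fitted lag
    correlations (lag 0 weight 1), renormalized over non-empty windows.
    Returns (value, weight) where weight is the fraction of non-empty
    windows; (nan, 0) when all windows are empty.
    """
    if variable not in windows:
        raise KeyError(f"no window config entry for {variable!r}")
    w = windows.window_size_h(variable)
    n = windows.n_windows(variable)
    r = [1.0] + list(windows.correlations.get(variable, [1.0] * (n - 1)))[: n - 1]
    r = (r + [1.0] * n)[:n]
    means = window_means(episode, variable, t, w, n)
    # only observations at or before t may contribute
    ok = ~np.isnan(means)
    if not ok.any():
        return float("nan"), 0.0
    weights = np.clip(np.asarray(r)[ok], 0.0, None)
    if weights.sum() <= 0:
        weights = np.ones(ok.sum())
    value = float(np.average(means[ok], weights=weights))
    return value, float(ok.mean())


def merge_estimates(
    mgp_value: float,
    ctwh_value: float,
    ctwh_weight: float,
    cfg: MgpConfig,
    fallback_value: float | None = None,
) -> tuple[float, str]:
    """Convex combination λ·ctwh + (1−λ)·mgp with provenance flag."""
    mgp_ok = np.isfinite(mgp_value)
    ctwh_ok = np.isfinite(ctwh_value) and ctwh_weight > 0
    if not mgp_ok and not ctwh_ok:
        if fallback_value is None:
            raise ValueError("both estimates undefined and no fallback supplied")
        return float(fallback_value), OUT_OF_SPAN
    if not ctwh_ok:
        return float(mgp_value), MGP
    if not mgp_ok:
        return float(ctwh_value), CTWH_MERGE
    lam = cfg.fixed_weight if cfg.merge_weight_mode == "fixed" else ctwh_weight * cfg.fixed_weight
    lam = float(np.clip(lam, 0.0, 1.0))
    return lam * ctwh_value + (1.0 - lam) * mgp_value, CTWH_MERGE if lam > 0 else MGP


def impute_episode(
    episode: Episode,
    panel: FeaturePanel,
    windows: WindowConfig,
    cfg: MgpConfig | None = None,
    hypers: MgpHyperparameters | None = None,
    cutoff_h: float | None = None,
    grid_hours: float = 12.0,
    grid_step_h: float = 1.0,
) -> ImputedGrid:
    """Full dual-step imputation onto the trailing hourly grid
    [cutoff − grid_hours, cutoff]."""
    cfg = cfg or MgpConfig()
    cutoff = episode.reference_time_h if cutoff_h is None else cutoff_h
    posterior = fit_mgp(episode, panel, windows, cfg, hypers, cutoff)
    n_steps = int(round(grid_hours / grid_step_h))
    grid_times = cutoff - grid_hours + grid_step_h * np.arange(n_steps + 1)
    grid = impute_grid(posterior, grid_times, windows)
    for j, code in enumerate(grid.variables):
        if code not in windows:
            continue
        for k, t in enumerate(grid_times):
            if grid.source[j, k] == OUT_OF_SPAN:
                continue
            c_val, c_w = ctwh_estimate(episode, code, windows, float(min(t, cutoff)))
            merged, flag = merge_estimates(
                grid.values[j, k], c_val, c_w, cfg, fallback_value=posterior.hp.medians[j]
            )
            grid.values[j, k] = merged
            if grid.source[j, k] != OBSERVED:
                grid.source[j, k] = flag
    return grid
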