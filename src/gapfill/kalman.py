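"""Linear-Gaussian state-space machinery for smoothing-based imputation.

Two classical families back the Kalman imputation baselines:

* **Kalman-Struct** — the basic structural model (BSM): local linear trend
  (level μ_t + slope β_t) plus a dummy-seasonal component γ_t whose values
  over one period sum to white noise. State dimension 2 + (s − 1) for
  seasonal period s.
* **Kalman-ARIMA** — ARIMA(p, d, q) in the Harvey companion state-space form
  (state dimension max(p, q+1)), with d integration levels added by state
  augmentation.

The filter handles missing observations by skipping the measurement update
(the filtered moments equal the one-step prediction), and the Gaussian
log-likelihood accumulates over observed steps only. The Rauch–Tung–Striebel
(RTS) backward pass then conditions every state on the full observation set,
which is what turns a fitted model into an imputer: a missing y_t is
estimated by Z·a_{t|n} with variance Z·P_{t|n}·Zᵀ + H.

Variance parameters of the BSM are estimated by maximum likelihood on the
prediction-error decomposition (quasi-Newton on log-variances, so positivity
holds by construction). ARIMA coefficients and AIC-based order selection are
delegated to ``statsmodels`` SARIMAX; the fitted coefficients are then placed
in this module's state space so that imputation always flows through the
same smoother.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.optimize

from .series import GapSpec, RegularSeries

DIFFUSE_KAPPA = 1e7


@dataclass
class StateSpaceModel:
    """Time-invariant linear-Gaussian state space.

    a_t = T a_{t-1} + R η_t,  η_t ~ N(0, Q)
    y_t = Z a_t + ε_t,        ε_t ~ N(0, H)
    """

    T: np.ndarray          # (k, k)
    Z: np.ndarray          # (k,)
    R: np.ndarray          # (k, q)
    Q: np.ndarray          # (q, q)
    H: float
    a0: np.ndarray | None = None
    P0: np.ndarray | None = None

    def __post_init__(self):
        self.T = np.atleast_2d(np.asarray(self.T, dtype=float))
        self.Z = np.asarray(self.Z, dtype=float).ravel()
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        k = self.T.shape[0]
        if self.T.shape != (k, k) or self.Z.shape != (k,):
            raise ValueError("inconsistent T/Z dimensions")
        if self.R.shape[0] != k or self.Q.shape != (self.R.shape[1],) * 2:
            raise ValueError("inconsistent R/Q dimensions")
        if self.H < 0:
            raise ValueError("H must be >= 0")
        if self.a0 is None:
            self.a0 = np.zeros(k)
        if self.P0 is None:
            self.P0 = DIFFUSE_KAPPA * np.eye(k)
        self.a0 = np.asarray(self.a0, dtype=float).ravel()
        self.P0 = np.atleast_2d(np.asarray(self.P0, dtype=float))

    @property
    def k(self) -> int:
        return self.T.shape[0]

    def state_noise_cov(self) -> np.ndarray:
        return self.R @ self.Q @ self.R.T


@dataclass(frozen=True)
class BsmSpec:
    """Basic structural model family; ``None`` variance = free (to be fitted).

    ``with_slope`` / ``with_seasonal`` turn components off (a local-level
    model is the family member with both off).
    """

    s: int = 48
    var_level: float | None = None
    var_slope: float | None = None
    var_seasonal: float | None = None
    var_obs: float | None = None
    with_slope: bool = True
    with_seasonal: bool = True

    def __post_init__(self):
        if self.with_seasonal and self.s < 2:
            raise ValueError("seasonal period s must be >= 2")

    @property
    def free_params(self) -> list[str]:
        names = [("var_level", True), ("var_slope", self.with_slope),
                 ("var_seasonal", self.with_seasonal), ("var_obs", True)]
        return [n for n, used in names if used and getattr(self, n) is None]


@dataclass(frozen=True)
class ArimaSpec:
    """ARIMA(p, d, q) family; ``None`` coefficients = free (to be fitted)."""

    p: int = 0
    d: int = 0
    q: int = 0
    ar_coeffs: tuple | None = None
    ma_coeffs: tuple | None = None
    sigma2: float | None = None

    def __post_init__(self):
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("orders must be nonnegative")
        if self.ar_coeffs is not None and len(self.ar_coeffs) != self.p:
            raise ValueError("ar_coeffs length must equal p")
        if self.ma_coeffs is not None and len(self.ma_coeffs) != self.q:
            raise ValueError("ma_coeffs length must equal q")

    @property
    def is_concrete(self) -> bool:
        return ((self.p == 0 or self.ar_coeffs is not None)
                and (self.q == 0 or self.ma_coeffs is not None)
                and self.sigma2 is not None)


@dataclass
class FilterResult:
    predicted_means: np.ndarray   # (n, k) a_{t|t-1}
    predicted_covs: np.ndarray    # (n, k, k)
    filtered_means: np.ndarray    # (n, k) a_{t|t}
    filtered_covs: np.ndarray     # (n, k, k)
    loglik: float


@dataclass
class SmootherResult:
    filtered_means: np.ndarray
    filtered_covs: np.ndarray
    smoothed_means: np.ndarray    # (n, k) a_{t|n}
    smoothed_covs: np.ndarray     # (n, k, k) P_{t|n}
    loglik: float


@dataclass
class ImputationResult:
    filled: np.ndarray            # series values with missing slots estimated
    variance: np.ndarray          # per-position estimation variance (0 where observed)
    spec: object                  # the (fitted) family spec actually used
    loglik: float
    converged: bool = True


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

def bsm_state_space(spec: BsmSpec) -> StateSpaceModel:
    """Assemble the BSM state space: level/slope block + dummy seasonal block.

    For s = 4 with all components on, T is the 5×5 matrix with level/slope
    block [[1, 1], [0, 1]] and a 3×3 seasonal block whose first row is all −1
    over a shifted identity; Z = [1, 0, 1, 0, 0].
    """
    vl = spec.var_level or 0.0
    vs = spec.var_slope or 0.0
    vw = spec.var_seasonal or 0.0
    vo = spec.var_obs or 0.0

    blocks, z_parts, q_diag = [], [], []
    # level (+ optional slope)
    if spec.with_slope:
        blocks.append(np.array([[1.0, 1.0], [0.0, 1.0]]))
        z_parts.append([1.0, 0.0])
    else:
        blocks.append(np.array([[1.0]]))
        z_parts.append([1.0])
    if spec.with_seasonal:
        d = spec.s - 1
        seas = np.zeros((d, d))
        seas[0, :] = -1.0
        if d > 1:
            seas[1:, :-1] = np.eye(d - 1)
        blocks.append(seas)
        z_parts.append([1.0] + [0.0] * (d - 1))

    k = sum(b.shape[0] for b in blocks)
    T = np.zeros((k, k))
    i = 0
    for b in blocks:
        T[i:i + b.shape[0], i:i + b.shape[0]] = b
        i += b.shape[0]
    Z = np.concatenate(z_parts)

    # noise loading: level shock, slope shock, seasonal shock
    cols = [(0, vl)]
    if spec.with_slope:
        cols.append((1, vs))
    if spec.with_seasonal:
        cols.append((2 if spec.with_slope else 1, vw))
    R = np.zeros((k, len(cols)))
    for j, (row, var) in enumerate(cols):
        R[row, j] = 1.0
        q_diag.append(var)
    return StateSpaceModel(T=T, Z=Z, R=R, Q=np.diag(q_diag), H=vo)


def arima_state_space(spec: ArimaSpec) -> StateSpaceModel:
    """Harvey companion form for ARIMA(p, d, q) with concrete coefficients.

    The ARMA core has state dimension r = max(p, q+1); each difference order
    adds one integration state on top.
    """
    if not spec.is_concrete:
        raise ValueError("arima_state_space needs concrete coefficients; use fit_ssm")
    ar = np.asarray(spec.ar_coeffs if spec.ar_coeffs else (), dtype=float)
    ma = np.asarray(spec.ma_coeffs if spec.ma_coeffs else (), dtype=float)
    if ar.size and np.abs(np.roots(np.r_[1.0, -ar])).max() >= 1.0 - 1e-10:
        raise ValueError("AR polynomial is not stationary")
    r = max(spec.p, spec.q + 1)
    phi = np.zeros(r)
    phi[:ar.size] = ar
    theta = np.zeros(r - 1)
    theta[:ma.size] = ma

    T = np.zeros((r, r))
    T[:, 0] = phi
    if r > 1:
        T[:-1, 1:] = np.eye(r - 1)
    Rmat = np.concatenate(([1.0], theta))[:, None]
    Z = np.zeros(r)
    Z[0] = 1.0

    # stationary initial covariance for the ARMA core
    RQRt = spec.sigma2 * (Rmat @ Rmat.T)
    P0_core = _solve_stationary_cov(T, RQRt)
    a0 = np.zeros(r)
    P0 = P0_core

    for _ in range(spec.d):
        k = T.shape[0]
        T_aug = np.zeros((k + 1, k + 1))
        T_aug[0, 0] = 1.0
        T_aug[0, 1:] = Z @ T
        T_aug[1:, 1:] = T
        R_aug = np.vstack([Z @ Rmat, Rmat])
        Z_aug = np.zeros(k + 1)
        Z_aug[0] = 1.0
        T, Rmat, Z = T_aug, R_aug, Z_aug
        a0 = np.concatenate(([0.0], a0))
        P0_new = np.zeros((k + 1, k + 1))
        P0_new[0, 0] = DIFFUSE_KAPPA
        P0_new[1:, 1:] = P0
        P0 = P0_new

    return StateSpaceModel(T=T, Z=Z, R=Rmat, Q=np.array([[spec.sigma2]]),
                           H=0.0, a0=a0, P0=P0)


def _solve_stationary_cov(T: np.ndarray, RQRt: np.ndarray) -> np.ndarray:
    """P = T P Tᵀ + RQRᵀ via the vectorized linear system."""
    k = T.shape[0]
    A = np.eye(k * k) - np.kron(T, T)
    vec = np.linalg.solve(A, RQRt.ravel())
    P = vec.reshape(k, k)
    return (P + P.T) / 2


def simulate_ssm(ssm: StateSpaceModel, n: int, rng=None,
                 state_shocks: np.ndarray | None = None,
                 obs_noise: np.ndarray | None = None,
                 a_init: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw (y, states) from the model; shocks may be supplied for replay."""
    if rng is None:
        rng = np.random.default_rng(0)
    k, q = ssm.k, ssm.R.shape[1]
    if state_shocks is None:
        w, V = np.linalg.eigh(ssm.Q)          # PSD factor; exact zeros stay zero
        Lq = V * np.sqrt(np.clip(w, 0.0, None))
        state_shocks = rng.standard_normal((n, q)) @ Lq.T
    if obs_noise is None:
        obs_noise = rng.normal(0.0, np.sqrt(ssm.H), size=n) if ssm.H > 0 else np.zeros(n)
    a = np.zeros(k) if a_init is None else np.asarray(a_init, dtype=float)
    states = np.empty((n, k))
    y = np.empty(n)
    for t in range(n):
        a = ssm.T @ a + ssm.R @ state_shocks[t]
        states[t] = a
        y[t] = ssm.Z @ a + obs_noise[t]
    return y, states


# ---------------------------------------------------------------------------
# filter / smoother
# ---------------------------------------------------------------------------

def _as_values(y) -> np.ndarray:
    return y.values if isinstance(y, RegularSeries) else np.asarray(y, dtype=float)


def kalman_filter(ssm: StateSpaceModel, y) -> FilterResult:
    """Forward predict/update recursion; missing y_t skips the update."""
    yv = _as_values(y)
    if np.isinf(yv).any():
        raise ValueError("non-finite (infinite) observations")
    n, k = yv.size, ssm.k
    T, Z, H = ssm.T, ssm.Z, ssm.H
    RQRt = ssm.state_noise_cov()

    pm = np.empty((n, k)); pc = np.empty((n, k, k))
    fm = np.empty((n, k)); fc = np.empty((n, k, k))
    a, P = ssm.a0, ssm.P0
    loglik = 0.0
    for t in range(n):
        a_pred = T @ a
        P_pred = T @ P @ T.T + RQRt
        P_pred = (P_pred + P_pred.T) / 2
        pm[t], pc[t] = a_pred, P_pred
        if np.isnan(yv[t]):
            a, P = a_pred, P_pred
        else:
            v = yv[t] - Z @ a_pred
            PZ = P_pred @ Z
            F = Z @ PZ + H
            loglik += -0.5 * (np.log(2 * np.pi) + np.log(F) + v * v / F)
            K = PZ / F
            a = a_pred + K * v
            P = P_pred - np.outer(K, PZ)
            P = (P + P.T) / 2
        fm[t], fc[t] = a, P
    return FilterResult(pm, pc, fm, fc, float(loglik))


def rts_smooth(ssm: StateSpaceModel, filtered: FilterResult) -> SmootherResult:
    """Rauch–Tung–Striebel backward pass conditioning on all observations."""
    T = ssm.T
    n, k = filtered.filtered_means.shape
    sm = np.empty((n, k)); sc = np.empty((n, k, k))
    sm[-1] = filtered.filtered_means[-1]
    sc[-1] = filtered.filtered_covs[-1]
    for t in range(n - 2, -1, -1):
        P_pred = filtered.predicted_covs[t + 1]
        try:
            J = np.linalg.solve(P_pred.T, (filtered.filtered_covs[t] @ T.T).T).T
        except np.linalg.LinAlgError:
            warnings.warn("singular predicted covariance; ridge-stabilizing")
            ridge = 1e-9 * max(np.trace(P_pred) / k, 1.0)
            J = filtered.filtered_covs[t] @ T.T @ np.linalg.inv(P_pred + ridge * np.eye(k))
        sm[t] = filtered.filtered_means[t] + J @ (sm[t + 1] - filtered.predicted_means[t + 1])
        P = filtered.filtered_covs[t] + J @ (sc[t + 1] - P_pred) @ J.T
        sc[t] = (P + P.T) / 2
    return SmootherResult(filtered.filtered_means, filtered.filtered_covs,
                          sm, sc, filtered.loglik)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    spec: object
    smoother: SmootherResult
    loglik: float
    converged: bool
    message: str = ""


def fit_ssm(y, family, max_points: int | None = None) -> FitResult:
    """Maximum-likelihood fit of a state-space family to a (gappy) series.

    BSM: quasi-Newton (L-BFGS-B) on log-variances of the free components,
    using this module's filter log-likelihood. ARIMA: coefficients fitted via
    statsmodels SARIMAX, then re-expressed in the Harvey form here. The final
    smoother pass always runs through :func:`rts_smooth`.

    ``max_points`` optionally restricts the *fitting* data to the last that
    many points (the smoother still runs on the full series).
    """
    yv = _as_values(y)
    y_fit = yv if max_points is None else yv[-max_points:]
    if isinstance(family, BsmSpec):
        fitted, ok, msg = _fit_bsm(y_fit, family)
        ssm = bsm_state_space(fitted)
    elif isinstance(family, ArimaSpec):
        fitted, ok, msg = (family, True, "coefficients supplied") if family.is_concrete \
            else _fit_arima(y_fit, family)
        ssm = arima_state_space(fitted)
    else:
        raise TypeError(f"unknown family {type(family).__name__}")
    n_obs = np.count_nonzero(~np.isnan(yv))
    if n_obs <= ssm.k * 10:
        raise ValueError(f"need > {ssm.k * 10} observed points, got {n_obs}")
    smoother = rts_smooth(ssm, kalman_filter(ssm, yv))
    return FitResult(spec=fitted, smoother=smoother, loglik=smoother.loglik,
                     converged=ok, message=msg)


def _fit_bsm(yv: np.ndarray, spec: BsmSpec) -> tuple[BsmSpec, bool, str]:
    free = spec.free_params
    if not free:
        return spec, True, "all variances fixed"
    var_y = float(np.nanvar(yv))
    var_y = var_y if var_y > 0 else 1.0
    start = {"var_level": 0.1 * var_y, "var_slope": 1e-4 * var_y,
             "var_seasonal": 1e-3 * var_y, "var_obs": 0.5 * var_y}
    x0 = np.log([start[name] for name in free])

    def build(x):
        values = dict(zip(free, np.exp(x)))
        return replace(spec, **values)

    def nll(x):
        ssm = bsm_state_space(build(x))
        ll = kalman_filter(ssm, yv).loglik
        return -ll if np.isfinite(ll) else 1e12

    res = scipy.optimize.minimize(nll, x0, method="L-BFGS-B",
                                  bounds=[(-30.0, 10.0)] * len(free),
                                  options={"maxiter": 200})
    return build(res.x), bool(res.success), str(res.message)


def _fit_arima(yv: np.ndarray, spec: ArimaSpec) -> tuple[ArimaSpec, bool, str]:
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(yv, order=(spec.p, spec.d, spec.q),
                        enforce_stationarity=True, enforce_invertibility=True)
        res = model.fit(disp=False, low_memory=True)
    ar = tuple(float(v) for v in res.arparams) if spec.p else None
    ma = tuple(float(v) for v in res.maparams) if spec.q else None
    sigma2 = float(res.params[-1])
    fitted = replace(spec, ar_coeffs=ar, ma_coeffs=ma, sigma2=sigma2)
    ok = bool(res.mle_retvals.get("converged", True)) if hasattr(res, "mle_retvals") else True
    return fitted, ok, "SARIMAX MLE"


def select_arima_order(y, p_max: int = 3, d_max: int = 1, q_max: int = 3,
                       max_points: int | None = None) -> ArimaSpec:
    """Pick (p, d, q) by AIC over a small grid (skips failed fits)."""
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    yv = _as_values(y)
    if max_points is not None:
        yv = yv[-max_points:]
    best, best_aic = None, np.inf
    for d in range(d_max + 1):
        for p in range(p_max + 1):
            for q in range(q_max + 1):
                if p == 0 and q == 0:
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = SARIMAX(yv, order=(p, d, q),
                                      enforce_stationarity=True,
                                      enforce_invertibility=True).fit(
                                          disp=False, low_memory=True)
                    if res.aic < best_aic:
                        best, best_aic = (p, d, q), res.aic
                except Exception:
                    continue
    if best is None:
        raise RuntimeError("no ARIMA order could be fitted")
    return ArimaSpec(p=best[0], d=best[1], q=best[2])


def impute_kalman(y, family, gap: GapSpec | None = None,
                  max_fit_points: int | None = None) -> ImputationResult:
    """Fill missing positions with smoothed estimates Z·a_{t|n}.

    Observed positions are returned bit-identical; the per-position variance
    Z·P_{t|n}·Zᵀ + H is reported everywhere (0 at observed positions).
    """
    yv = _as_values(y)
    fit = fit_ssm(yv, family, max_points=max_fit_points)
    if isinstance(family, BsmSpec):
        ssm = bsm_state_space(fit.spec)
    else:
        ssm = arima_state_space(fit.spec)
    sm = fit.smoother
    est = sm.smoothed_means @ ssm.Z
    var = np.einsum("i,tij,j->t", ssm.Z, sm.smoothed_covs, ssm.Z) + ssm.H
    missing = np.isnan(yv)
    filled = np.where(missing, est, yv)
    var = np.where(missing, var, 0.0)
    return ImputationResult(filled=filled, variance=var, spec=fit.spec,
                            loglik=fit.loglik, converged=fit.converged)
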