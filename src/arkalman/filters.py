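"""Adaptive Kalman filtering of AR state-space models.

The filter family runs on the (A, H, Q, R) model from
:mod:`.state_space` and differs only in how the noise statistics evolve:

``KF``
    Plain Kalman filter: fading factor fixed at 1, Q and R fixed.
``SHKF``
    Sage-Husa adaptive filter: the process-noise covariance Q is
    re-estimated each step from the innovation sequence with a
    forgetting-weighted recursion; R stays fixed (the joint Q-and-R
    estimator is unreliable and only available behind ``adapt_R``).
``STKF``
    Strong-tracking filter: the predicted covariance is inflated by a
    fading factor lambda_k >= 1 computed from the ratio of
    innovation-based to model-based covariance traces; Q and R fixed.
``STSHKF``
    Strong tracking and Sage-Husa Q adaptation combined — the adaptive
    filter used for EMG denoising.

All variants use the Joseph-form covariance update and symmetrise P each
step, so P stays symmetric positive semidefinite.  A fixed-interval
Rauch-Tung-Striebel smoother (:func:`rts_smooth`) refines a completed
forward pass for offline use.

Conventions: the first measurement is step k = 0; the forgetting weight
d_k = (1 - b) / (1 - b^(k+1)) therefore equals 1 at k = 0 (the first
innovation is fully trusted) and decreases to its limit 1 - b.  The
denoised output at step k is H @ x_hat_k plus the signal mean removed
during fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .signal import Signal
from .state_space import StateSpaceModel

logger = logging.getLogger(__name__)

VARIANTS = ("KF", "SHKF", "STKF", "STSHKF")


class FilterConfigError(ValueError):
    """Invalid filter hyperparameters."""


class DivergenceError(RuntimeError):
    """Filter state became non-finite."""

    def __init__(self, step: int, message: str) -> None:
        super().__init__(f"step {step}: {message}")
        self.step = step


class DegeneracyError(RuntimeError):
    """Innovation covariance lost positivity beyond recovery."""


@dataclass(frozen=True)
class FilterConfig:
    """Hyperparameters of the adaptive filter.

    Parameters
    ----------
    variant
        One of ``KF``, ``SHKF``, ``STKF``, ``STSHKF``.
    b
        Forgetting factor in (0, 1); the usual range is 0.95-0.99.
        Controls how fast old innovations are down-weighted in the
        Sage-Husa recursion.
    rho
        Innovation-covariance memory factor in (0, 1] for the fading
        factor's smoothed innovation outer product.
    beta
        Softening factor >= 1; scales R inside the fading-factor
        numerator, damping the inflation.
    adapt_R
        Also re-estimate R jointly with Q (off by default: the joint
        estimator is known to be unreliable and can destroy positive
        definiteness).
    q_floor
        Absolute floor for the adapted Q's diagonal; ``None`` derives it
        from the model's signal variance.
    x0, P0
        Initial state and covariance.  ``None`` uses the mean of the
        first n (centred) samples for every state component and
        10 * var(signal) * I.
    """

    variant: str = "STSHKF"
    b: float = 0.97
    rho: float = 0.95
    beta: float = 1.0
    adapt_R: bool = False
    q_floor: float | None = None
    x0: np.ndarray | None = None
    P0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise FilterConfigError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if not (0.0 < self.b < 1.0):
            raise FilterConfigError(f"b must be in (0,1), got {self.b}")
        if not (0.0 < self.rho <= 1.0):
            raise FilterConfigError(f"rho must be in (0,1], got {self.rho}")
        if self.beta < 1.0:
            raise FilterConfigError(f"beta must be >= 1, got {self.beta}")
        if self.P0 is not None:
            P0 = np.atleast_2d(np.asarray(self.P0, dtype=float))
            if not np.allclose(P0, P0.T):
                raise FilterConfigError("P0 must be symmetric")
            if np.any(np.linalg.eigvalsh(P0) < -1e-12 * max(1.0, P0.max())):
                raise FilterConfigError("P0 must be positive semidefinite")

    @property
    def adapts_q(self) -> bool:
        return self.variant in ("SHKF", "STSHKF")

    @property
    def strong_tracking(self) -> bool:
        return self.variant in ("STKF", "STSHKF")


@dataclass(frozen=True)
class FilterResult:
    """Per-step output of a forward filter pass.

    ``denoised`` is H @ x_hat per step with the signal mean restored;
    ``x_pred``/``P_pred`` store the one-step predictions needed by the
    smoother.
    """

    x_filtered: np.ndarray   # (N, n)
    P_filtered: np.ndarray   # (N, n, n)
    x_pred: np.ndarray       # (N, n)
    P_pred: np.ndarray       # (N, n, n)
    innovations: np.ndarray  # (N,)
    lambdas: np.ndarray      # (N,)
    q_trace: np.ndarray      # (N,)
    denoised: Signal
    model: StateSpaceModel
    config: FilterConfig
    warnings: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SmootherResult:
    """Backward-pass refinement of a forward filter result."""

    x_smoothed: np.ndarray
    P_smoothed: np.ndarray
    denoised: Signal
    forward: FilterResult


def forgetting_weight(k: int, b: float) -> float:
    """Sage-Husa forgetting weight d_k = (1 - b) / (1 - b^(k+1)).

    Strictly decreasing in k, from d_0 = 1 down to the limit 1 - b.
    """
    if not (0.0 < b < 1.0):
        raise FilterConfigError(f"b must be in (0,1), got {b}")
    if k < 0:
        raise ValueError(f"step index must be >= 0, got {k}")
    return (1.0 - b) / (1.0 - b ** (k + 1))


def fading_factor(V_k: float, V0_prev: float, model: StateSpaceModel,
                  P_prev: np.ndarray, Q_prev: np.ndarray, R_k: float,
                  cfg: FilterConfig, k: int) -> tuple[float, float]:
    """Strong-tracking fading factor lambda_k and updated innovation memory.

    The innovation outer-product memory is V0(0) = V_0^2 and, for k > 0,
    V0(k) = (rho V0(k-1) + V_k^2) / (1 + rho).  The factor compares the
    innovation-based excess N_k = V0(k) - H Q H' - beta R against the
    model-based M_k = H A P A' H' and clamps the ratio at 1:

        lambda_k = max(tr(N_k) / tr(M_k), 1)

    A non-positive tr(M_k) (degenerate geometry) yields lambda_k = 1 with
    a logged warning.
    """
    v2 = float(V_k) ** 2
    if k == 0:
        return 1.0, v2
    V0_new = (cfg.rho * V0_prev + v2) / (1.0 + cfg.rho)
    H, A = model.H, model.A
    N_k = V0_new - H @ Q_prev @ H - cfg.beta * R_k
    M_k = float(H @ A @ P_prev @ A.T @ H)
    if M_k <= 0.0:
        logger.warning("step %d: tr(M) = %.3g <= 0; fading factor forced to 1",
                       k, M_k)
        return 1.0, V0_new
    return max(N_k / M_k, 1.0), V0_new


def adapt_Q(Q_prev: np.ndarray, d_k: float, K_prev: np.ndarray, V_k: float,
            A: np.ndarray, P_prev: np.ndarray,
            q_floor: float = 0.0) -> np.ndarray:
    """Sage-Husa process-noise update (Q only, R fixed).

    Q_k = (1 - d_k) Q_{k-1} + d_k (K_{k-1} V_k V_k' K_{k-1}' + A P_{k-1} A'),
    with the diagonal floored at ``q_floor``.
    """
    K = np.asarray(K_prev, dtype=float).ravel()
    Q = (1.0 - d_k) * Q_prev + d_k * (
        float(V_k) ** 2 * np.outer(K, K) + A @ P_prev @ A.T)
    Q = 0.5 * (Q + Q.T)
    if q_floor > 0.0:
        d = np.diag(Q).copy()
        np.fill_diagonal(Q, np.maximum(d, q_floor))
    return Q


def kf_step(x: np.ndarray, P: np.ndarray, z: float, model: StateSpaceModel,
            lam: float = 1.0, Q: np.ndarray | None = None,
            R: float | None = None, k: int = 0) -> tuple[np.ndarray,
                                                         np.ndarray, dict]:
    """One predict/update cycle on a centred observation z.

    Predict x_pred = A x (no control input); innovation V = z - H x_pred;
    faded prediction covariance P_pred = lam * A P A' + Q; gain K; state
    update; Joseph-form covariance update
    P = (I - K H) P_pred (I - K H)' + K R K', then symmetrisation.

    Returns the updated (x, P) and a diagnostics dict with the innovation,
    gain, innovation variance and the prediction pair.
    """
    A, H = model.A, model.H
    Q = model.Q if Q is None else Q
    R = model.R if R is None else R
    x_pred = A @ x
    V = float(z - H @ x_pred)
    if not np.isfinite(V):
        raise DivergenceError(k, "non-finite innovation")
    P_pred = lam * (A @ P @ A.T) + Q
    S = float(H @ P_pred @ H + R)
    if S <= 0.0:
        raise DegeneracyError(
            f"step {k}: innovation covariance {S:.3g} <= 0")
    K = (P_pred @ H) / S
    x_new = x_pred + K * V
    IKH = np.eye(model.n) - np.outer(K, H)
    P_new = IKH @ P_pred @ IKH.T + R * np.outer(K, K)
    P_new = 0.5 * (P_new + P_new.T)
    diag = {"V": V, "K": K, "S": S, "x_pred": x_pred, "P_pred": P_pred}
    return x_new, P_new, diag


def run_filter(signal: Signal, model: StateSpaceModel,
               cfg: FilterConfig | None = None) -> FilterResult:
    """Filter a signal through the state-space model with one variant.

    Observations are centred with the model's stored mean; the denoised
    output H @ x_hat has the mean restored.  Dispatch by variant:
    ``KF`` fixes lambda, Q and R; ``SHKF`` adapts Q; ``STKF`` computes the
    fading factor; ``STSHKF`` does both.
    """
    cfg = cfg or FilterConfig()
    n = model.n
    N = len(signal)
    if N <= n:
        raise ValueError(f"signal length {N} must exceed state dimension {n}")
    z = signal.samples - model.mean

    if cfg.x0 is not None:
        x = np.asarray(cfg.x0, dtype=float).ravel().copy()
        if x.shape != (n,):
            raise FilterConfigError(f"x0 must have shape ({n},)")
    else:
        x = np.full(n, float(np.mean(z[:n])))
    if cfg.P0 is not None:
        P = np.atleast_2d(np.asarray(cfg.P0, dtype=float)).copy()
        if P.shape != (n, n):
            raise FilterConfigError(f"P0 must have shape ({n},{n})")
    else:
        P = 10.0 * max(model.signal_var, np.finfo(float).tiny) * np.eye(n)

    q_floor = cfg.q_floor
    if q_floor is None:
        q_floor = 1e-12 * max(model.signal_var, 0.0)

    Q = model.Q.copy()
    R = float(model.R)
    R0 = float(model.R)
    V0 = 0.0
    K_prev: np.ndarray | None = None

    x_f = np.empty((N, n))
    P_f = np.empty((N, n, n))
    x_p = np.empty((N, n))
    P_p = np.empty((N, n, n))
    innovations = np.empty(N)
    lambdas = np.ones(N)
    q_trace = np.empty(N)
    warn_counts = {"fading_degenerate": 0, "innovation_degenerate": 0}

    for k in range(N):
        x_pred = model.A @ x
        V = float(z[k] - model.H @ x_pred)
        if not np.isfinite(V):
            raise DivergenceError(k, "non-finite innovation "
                                  f"(last finite state at step {k - 1})")
        d_k = forgetting_weight(k, cfg.b)

        lam = 1.0
        if cfg.strong_tracking:
            lam, V0_new = fading_factor(V, V0, model, P, Q, R, cfg, k)
            if lam == 1.0 and k > 0:
                M_k = float(model.H @ model.A @ P @ model.A.T @ model.H)
                if M_k <= 0.0:
                    warn_counts["fading_degenerate"] += 1
            V0 = V0_new

        if cfg.adapts_q and K_prev is not None:
            Q = adapt_Q(Q, d_k, K_prev, V, model.A, P, q_floor=q_floor)
        if cfg.adapt_R and K_prev is not None:
            r = 1.0 - float(model.H @ K_prev)
            R = d_k * (V * V * r * r + float(model.H @ P @ model.H)) \
                + (1.0 - d_k) * R

        P_pred = lam * (model.A @ P @ model.A.T) + Q
        S = float(model.H @ P_pred @ model.H + R)
        if S <= 0.0:
            # recover once with the unfaded covariance and the initial R
            warn_counts["innovation_degenerate"] += 1
            logger.warning("step %d: innovation covariance %.3g <= 0; "
                           "falling back to lambda=1, R0", k, S)
            lam = 1.0
            R = R0
            P_pred = model.A @ P @ model.A.T + Q
            S = float(model.H @ P_pred @ model.H + R)
            if S <= 0.0:
                raise DegeneracyError(
                    f"step {k}: innovation covariance {S:.3g} <= 0 "
                    "after fallback")
        K = (P_pred @ model.H) / S
        x = x_pred + K * V
        IKH = np.eye(n) - np.outer(K, model.H)
        P = IKH @ P_pred @ IKH.T + R * np.outer(K, K)
        P = 0.5 * (P + P.T)
        K_prev = K

        x_f[k] = x
        P_f[k] = P
        x_p[k] = x_pred
        P_p[k] = P_pred
        innovations[k] = V
        lambdas[k] = lam
        q_trace[k] = float(np.trace(Q))

    if not np.all(np.isfinite(x_f)):
        bad = int(np.argmax(~np.isfinite(x_f).all(axis=1)))
        raise DivergenceError(bad, "non-finite state estimate")

    denoised = signal.with_samples(x_f @ model.H + model.mean)
    return FilterResult(x_filtered=x_f, P_filtered=P_f, x_pred=x_p,
                        P_pred=P_p, innovations=innovations, lambdas=lambdas,
                        q_trace=q_trace, denoised=denoised, model=model,
                        config=cfg, warnings=warn_counts)


def rts_smooth(result: FilterResult,
               model: StateSpaceModel | None = None) -> SmootherResult:
    """Fixed-interval Rauch-Tung-Striebel backward pass.

    Runs the classical smoother over a completed forward pass:

        C_k      = P_k A' inv(P_{k+1|k})
        x_{k|N}  = x_k + C_k (x_{k+1|N} - x_{k+1|k})
        P_{k|N}  = P_k + C_k (P_{k+1|N} - P_{k+1|k}) C_k'

    The last step is anchored at the filtered estimate.  A singular
    predicted covariance falls back to the pseudo-inverse with a logged
    warning.
    """
    model = model or result.model
    A, H = model.A, model.H
    N, n = result.x_filtered.shape
    x_s = result.x_filtered.copy()
    P_s = result.P_filtered.copy()
    for k in range(N - 2, -1, -1):
        Pp = result.P_pred[k + 1]
        PA = result.P_filtered[k] @ A.T
        try:
            C = np.linalg.solve(Pp.T, PA.T).T
        except np.linalg.LinAlgError:
            logger.warning("step %d: singular predicted covariance; "
                           "using pseudo-inverse", k + 1)
            C = PA @ np.linalg.pinv(Pp)
        x_s[k] = result.x_filtered[k] + C @ (x_s[k + 1] - result.x_pred[k + 1])
        P = result.P_filtered[k] + C @ (P_s[k + 1] - Pp) @ C.T
        P_s[k] = 0.5 * (P + P.T)
    denoised = result.denoised.with_samples(x_s @ H + model.mean)
    return SmootherResult(x_smoothed=x_s, P_smoothed=P_s, denoised=denoised,
                          forward=result)
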