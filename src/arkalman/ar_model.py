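"""Autoregressive model fitting and order selection.

An AR(n) model expresses each sample as a linear combination of its n
predecessors plus white innovation noise:

    x_t = phi_1 x_{t-1} + ... + phi_n x_{t-n} + eps_t,   eps_t ~ N(0, sigma2)

Coefficients are estimated by ordinary least squares on the lagged design
matrix; the innovation variance is the mean squared residual with divisor
N - n.  The model order is selected by minimising information criteria
(AIC, BIC, FPE) over a range of candidate orders.

Signals are mean-centred before fitting (the AR model carries no
intercept); the removed mean is stored on the fitted model so downstream
reconstruction can restore it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import Signal

#: condition-number threshold on X'X above which the fit is refused
COND_THRESHOLD = 1e12

#: relative floor applied to a zero residual variance before taking logs
SIGMA2_FLOOR_REL = 1e-15

CRITERIA = ("AIC", "BIC", "FPE")


class InsufficientDataError(ValueError):
    """Signal too short for the requested model order."""


class RankDeficiencyError(np.linalg.LinAlgError):
    """Lagged design matrix is singular or numerically ill-conditioned."""


@dataclass(frozen=True)
class ARModel:
    """A fitted AR(n) model.

    Attributes
    ----------
    order
        Model order n (number of lags).
    phi
        Coefficient vector (phi_1 ... phi_n), dimensionless.
    sigma2
        Residual (innovation) variance, in squared signal units.
    mean
        Sample mean removed from the signal before fitting.
    """

    order: int
    phi: np.ndarray
    sigma2: float
    mean: float = 0.0

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float).ravel()
        object.__setattr__(self, "phi", phi)
        if phi.size != self.order or self.order < 1:
            raise ValueError(
                f"phi has {phi.size} coefficients for order {self.order}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")

    def predict(self, samples: np.ndarray) -> np.ndarray:
        """One-step-ahead predictions for ``samples[order:]`` (centred)."""
        x = np.asarray(samples, dtype=float) - self.mean
        X = _lag_matrix(x, self.order)
        return X @ self.phi + self.mean


@dataclass(frozen=True)
class OrderSelectionResult:
    """Criterion table and selected order from an order sweep."""

    criteria: pd.DataFrame  # columns: n, AIC, BIC, FPE
    n_star: int
    per_criterion_argmin: dict = field(default_factory=dict)

    @property
    def n_max(self) -> int:
        return int(self.criteria["n"].max())


def _lag_matrix(x: np.ndarray, n: int) -> np.ndarray:
    """(N-n) x n design matrix; column j holds lag j+1, rows t = n..N-1."""
    N = x.size
    return np.column_stack([x[n - j - 1 : N - j - 1] for j in range(n)])


def fit_ar_least_squares(signal: Signal, n: int, center: bool = True) -> ARModel:
    """Fit an AR(n) model by ordinary least squares.

    Solves the normal equations (X'X)^{-1} X'Y where X stacks the n lagged
    copies of the signal and Y holds the samples being predicted.  The
    innovation variance is the mean squared residual with divisor N - n.

    By default the signal is mean-centred first (the model has no
    intercept term); the removed mean is stored on the fitted model.
    Pass ``center=False`` to fit the raw samples, e.g. for signals that
    satisfy an exact zero-intercept recurrence.

    Raises
    ------
    InsufficientDataError
        If the signal has fewer than 2n + 1 samples.
    RankDeficiencyError
        If X'X has condition number above ``COND_THRESHOLD``.
    """
    if n < 1:
        raise ValueError(f"order must be >= 1, got {n}")
    N = len(signal)
    if N <= 2 * n:
        raise InsufficientDataError(
            f"need > {2 * n} samples to fit AR({n}), got {N}")
    mean = float(np.mean(signal.samples)) if center else 0.0
    x = signal.samples - mean
    X = _lag_matrix(x, n)
    Y = x[n:]
    G = X.T @ X
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > COND_THRESHOLD:
        raise RankDeficiencyError(
            f"normal equations ill-conditioned for AR({n}): cond={cond:.3g}")
    phi = np.linalg.solve(G, X.T @ Y)
    resid = Y - X @ phi
    sigma2 = float(resid @ resid) / (N - n)
    return ARModel(order=n, phi=phi, sigma2=sigma2, mean=mean)


def estimate_noise_variance(signal: Signal, phi: np.ndarray,
                            mean: float = 0.0) -> float:
    """Residual variance of given AR coefficients on a signal.

    Returns (1/(N-n)) * sum_{t=n}^{N-1} (x_t - sum_i phi_i x_{t-i})^2 on
    the signal after removing ``mean``.
    """
    phi = np.asarray(phi, dtype=float).ravel()
    n = phi.size
    N = len(signal)
    if N <= n:
        raise InsufficientDataError(
            f"need more than {n} samples, got {N}")
    x = signal.samples - mean
    resid = x[n:] - _lag_matrix(x, n) @ phi
    return float(resid @ resid) / (N - n)


def criterion_value(kind: str, N: int, n: int, sigma2: float) -> float:
    """Evaluate one order-selection criterion.

    AIC(n) = N ln(sigma2) + 2n
    BIC(n) = N ln(sigma2) + n ln(N)
    FPE(n) = ((N + n) / (N - n)) sigma2
    """
    if not (N > n >= 1):
        raise ValueError(f"need N > n >= 1, got N={N}, n={n}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    kind = kind.upper()
    if kind == "AIC":
        return N * np.log(sigma2) + 2.0 * n
    if kind == "BIC":
        return N * np.log(sigma2) + n * np.log(N)
    if kind == "FPE":
        return (N + n) / (N - n) * sigma2
    raise ValueError(f"unknown criterion {kind!r}; expected one of {CRITERIA}")


def select_order(signal: Signal, n_max: int = 10) -> OrderSelectionResult:
    """Sweep orders 1..n_max and select the best by majority vote.

    Every order is fitted by least squares and all three criteria are
    recorded.  Each criterion nominates its argmin; the selected order is
    the majority vote of the three nominations, with ties broken toward
    the smallest nominated order (parsimony).  The full criterion table is
    returned so a caller can apply a different rule.

    A residual variance of exactly zero (perfect fit) is floored at
    ``SIGMA2_FLOOR_REL * var(signal)`` before the logarithm.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    N = len(signal)
    if N <= 2 * n_max:
        raise InsufficientDataError(
            f"need > {2 * n_max} samples for n_max={n_max}, got {N}")
    var = float(np.var(signal.samples))
    floor = SIGMA2_FLOOR_REL * var if var > 0 else SIGMA2_FLOOR_REL
    rows = []
    errors: dict[int, Exception] = {}
    for n in range(1, n_max + 1):
        try:
            model = fit_ar_least_squares(signal, n)
        except (InsufficientDataError, RankDeficiencyError) as exc:
            errors[n] = exc
            continue
        s2 = max(model.sigma2, floor)
        rows.append({
            "n": n,
            "AIC": criterion_value("AIC", N, n, s2),
            "BIC": criterion_value("BIC", N, n, s2),
            "FPE": criterion_value("FPE", N, n, s2),
        })
    if not rows:
        raise RankDeficiencyError(
            f"all orders 1..{n_max} failed to fit: {errors}")
    table = pd.DataFrame(rows)
    argmins = {
        c: int(table.loc[table[c].idxmin(), "n"]) for c in CRITERIA
    }
    votes = pd.Series(list(argmins.values())).value_counts()
    top = votes[votes == votes.max()].index
    n_star = int(min(top))
    return OrderSelectionResult(criteria=table, n_star=n_star,
                                per_criterion_argmin=argmins)
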