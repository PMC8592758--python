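"""Shared fixtures: an independent textbook Kalman filter oracle and a
linear-Gaussian state-space simulator used to cross-check the filters."""

from __future__ import annotations

import numpy as np
import pytest

from arkalman.state_space import StateSpaceModel


def textbook_kf(zs, A, H, Q, R, x0, P0):
    """Plain covariance-form Kalman filter, written independently of the
    package (matrix H, explicit inverse, no Joseph form, no fading).

    Returns (states, covariances) for the measurement sequence ``zs``.
    """
    A = np.atleast_2d(np.asarray(A, float))
    H = np.atleast_2d(np.asarray(H, float))  # 1 x n
    Q = np.atleast_2d(np.asarray(Q, float))
    R = np.atleast_2d(np.asarray(R, float))  # 1 x 1
    x = np.asarray(x0, float).reshape(-1, 1)
    P = np.atleast_2d(np.asarray(P0, float)).copy()
    xs, Ps = [], []
    for z in np.asarray(zs, float):
        x_pred = A @ x
        P_pred = A @ P @ A.T + Q
        S = H @ P_pred @ H.T + R
        K = P_pred @ H.T @ np.linalg.inv(S)
        x = x_pred + K @ (np.array([[z]]) - H @ x_pred)
        P = (np.eye(A.shape[0]) - K @ H) @ P_pred
        xs.append(x.ravel().copy())
        Ps.append(P.copy())
    return np.array(xs), np.array(Ps)


def simulate_linear_gaussian(model: StateSpaceModel, N: int, seed: int):
    """Draw states and observations from X' = A X + w, z = H X + v."""
    rng = np.random.default_rng(seed)
    n = model.n
    q_std = np.sqrt(np.diag(model.Q))
    r_std = np.sqrt(model.R)
    X = np.zeros((N, n))
    z = np.zeros(N)
    x = np.zeros(n)
    for k in range(N):
        x = model.A @ x + q_std * rng.standard_normal(n)
        X[k] = x
        z[k] = model.H @ x + r_std * rng.standard_normal()
    return X, z


@pytest.fixture
def kf_oracle():
    return textbook_kf


@pytest.fixture
def lg_simulator():
    return simulate_linear_gaussian


@pytest.fixture
def toy_model() -> StateSpaceModel:
    """A small stable 2-state model with known (A, H, Q, R)."""
    return StateSpaceModel(
        A=np.array([[0.9, 0.0], [0.2, 0.5]]),
        H=np.array([1.0, 0.3]),
        Q=np.diag([0.04, 0.09]),
        R=0.25,
        mean=0.0,
        signal_var=1.0,
    )
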