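"""Lift a family of AR fits into an n-dimensional state-space model.

The same signal is fitted with AR models of every order 1..n.  Stacking
the order-i coefficient rows yields a lower-triangular transition matrix
A; each state component i carries the order-i model's estimate of the
signal.  The process-noise covariance Q is diagonal with the per-order
residual variances, the observation row H is the order-n coefficient
vector, and the observation-noise variance R is the order-n residual
variance:

    A[i, j] = phi_{i+1, j+1}  (j <= i, zero above the diagonal band)
    Q       = diag(sigma2_1, ..., sigma2_n)
    H       = (phi_{n,1}, ..., phi_{n,n})
    R       = sigma2_n

The denoised signal downstream is defined as H @ x_hat, i.e. the
observation row applied to the filtered state (see :mod:`.filters`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ar_model import ARModel, fit_ar_least_squares
from .signal import Signal

#: relative floor for zero residual variances on Q's diagonal
Q_FLOOR_REL = 1e-12


class IncompleteGroupError(ValueError):
    """AR model group is missing an order or has inconsistent orders."""


@dataclass(frozen=True)
class ARModelGroup:
    """AR fits of orders 1..n to one signal; ``models[i]`` has order i+1."""

    models: tuple[ARModel, ...]

    def __post_init__(self) -> None:
        models = tuple(self.models)
        object.__setattr__(self, "models", models)
        if not models:
            raise IncompleteGroupError("empty AR model group")
        for i, m in enumerate(models, start=1):
            if m.order != i:
                raise IncompleteGroupError(
                    f"slot {i} holds an order-{m.order} model")

    @property
    def n(self) -> int:
        return len(self.models)

    def __getitem__(self, order: int) -> ARModel:
        """Model of the given order (1-based)."""
        return self.models[order - 1]


@dataclass(frozen=True)
class StateSpaceModel:
    """State-space form (A, H, Q, R) assembled from an AR model group.

    ``mean`` is the signal mean removed before fitting; filters subtract
    it from observations and restore it on the reconstructed output.
    ``signal_var`` is kept for relative numerical floors downstream.
    """

    A: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: float
    mean: float = 0.0
    signal_var: float = 1.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        H = np.asarray(self.H, dtype=float).ravel()
        Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "Q", Q)
        n = self.n
        if A.shape != (n, n) or H.shape != (n,) or Q.shape != (n, n):
            raise ValueError(
                f"inconsistent shapes: A{A.shape}, H{H.shape}, Q{Q.shape}")
        if self.R < 0:
            raise ValueError(f"R must be >= 0, got {self.R}")

    @property
    def n(self) -> int:
        return int(np.atleast_2d(self.A).shape[0])

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))


def build_ar_group(signal: Signal, n: int) -> ARModelGroup:
    """Fit AR models of every order 1..n to the same signal."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    models = []
    for order in range(1, n + 1):
        try:
            models.append(fit_ar_least_squares(signal, order))
        except Exception as exc:
            raise type(exc)(f"AR({order}) fit failed: {exc}") from exc
    return ARModelGroup(models=tuple(models))


def assemble_state_space(group: ARModelGroup,
                         signal_var: float | None = None) -> StateSpaceModel:
    """Assemble (A, H, Q, R) from a complete order-1..n AR group.

    Zero entries on Q's diagonal are floored at ``Q_FLOOR_REL`` times the
    signal variance to keep the downstream filter numerically alive.  A
    warning (not an error) is issued if A's spectral radius is >= 1,
    which indicates the fitted dynamics are not stationary.
    """
    n = group.n
    A = np.zeros((n, n))
    q = np.empty(n)
    for i in range(1, n + 1):
        model = group[i]
        A[i - 1, :i] = model.phi
        q[i - 1] = model.sigma2
    top = group[n]
    if signal_var is None:
        # residual variance is a lower bound on scale; fall back to it
        signal_var = max(float(np.max(q)), 1.0e-30)
    floor = Q_FLOOR_REL * signal_var
    q = np.maximum(q, floor)
    model = StateSpaceModel(A=A, H=top.phi.copy(), Q=np.diag(q),
                            R=float(max(top.sigma2, floor)),
                            mean=top.mean, signal_var=float(signal_var))
    if model.spectral_radius >= 1.0:
        warnings.warn(
            f"transition matrix spectral radius {model.spectral_radius:.4f}"
            " >= 1; fitted dynamics are non-stationary", RuntimeWarning,
            stacklevel=2)
    return model


def build_state_space(signal: Signal, n: int) -> StateSpaceModel:
    """Convenience: fit the order-1..n group and assemble in one call."""
    group = build_ar_group(signal, n)
    return assemble_state_space(group,
                                signal_var=float(np.var(signal.samples)))


def write_state_space(model: StateSpaceModel, path: str | Path) -> None:
    """Serialise a state-space model to a plain-text key-value block."""
    path = Path(path)
    with path.open("w") as fh:
        fmt = "{:.17g}".format
        fh.write(f"n = {model.n}\n")
        fh.write(f"mean = {fmt(model.mean)}\n")
        fh.write(f"signal_var = {fmt(model.signal_var)}\n")
        fh.write(f"R = {fmt(model.R)}\n")
        fh.write("H = " + " ".join(fmt(v) for v in model.H) + "\n")
        for i in range(model.n):
            fh.write(f"A{i} = " + " ".join(fmt(v) for v in model.A[i]) + "\n")
        fh.write("Qdiag = " + " ".join(fmt(v) for v in np.diag(model.Q)) + "\n")


def read_state_space(path: str | Path) -> StateSpaceModel:
    """Read a state-space model written by :func:`write_state_space`."""
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    n = int(fields["n"])
    A = np.array([[float(v) for v in fields[f"A{i}"].split()]
                  for i in range(n)])
    return StateSpaceModel(
        A=A,
        H=np.array([float(v) for v in fields["H"].split()]),
        Q=np.diag([float(v) for v in fields["Qdiag"].split()]),
        R=float(fields["R"]),
        mean=float(fields.get("mean", 0.0)),
        signal_var=float(fields.get("signal_var", 1.0)),
    )
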