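"""End-to-end denoising: order selection -> AR group -> state space -> filter.

This is the programmatic form of the full pipeline the CLI exposes:
select the AR order by information criteria (unless fixed), fit the
order-1..n model group, assemble the state-space model, run the chosen
adaptive-filter variant, and optionally apply the Rauch-Tung-Striebel
smoother for offline use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import filters
from .ar_model import OrderSelectionResult, select_order
from .signal import Signal
from .state_space import StateSpaceModel, build_state_space

#: pipeline variants; RTS = plain Kalman forward pass + RTS smoother
PIPELINE_VARIANTS = ("KF", "RTS", "SHKF", "STKF", "STSHKF")


@dataclass(frozen=True)
class DenoiseResult:
    """Everything produced by one denoising run."""

    denoised: Signal
    model: StateSpaceModel
    filter_result: filters.FilterResult
    smoother_result: filters.SmootherResult | None = None
    order_selection: OrderSelectionResult | None = None

    @property
    def n(self) -> int:
        return self.model.n


def denoise(signal: Signal, variant: str = "STSHKF", n: int | None = None,
            n_max: int = 10, b: float = 0.97, rho: float = 0.95,
            beta: float = 1.0, adapt_R: bool = False) -> DenoiseResult:
    """Denoise a signal with one filter variant.

    If ``n`` is None the AR order is selected by the AIC/BIC/FPE majority
    vote over 1..n_max; otherwise order selection is skipped.  Variant
    ``RTS`` runs the plain Kalman filter forward and refines it with the
    fixed-interval smoother; the other variants are forward-only.
    """
    if variant not in PIPELINE_VARIANTS:
        raise filters.FilterConfigError(
            f"unknown variant {variant!r}; expected one of {PIPELINE_VARIANTS}")
    order_selection = None
    if n is None:
        order_selection = select_order(signal, n_max=n_max)
        n = order_selection.n_star
    model = build_state_space(signal, n)
    fwd_variant = "KF" if variant == "RTS" else variant
    cfg = filters.FilterConfig(variant=fwd_variant, b=b, rho=rho, beta=beta,
                               adapt_R=adapt_R)
    fr = filters.run_filter(signal, model, cfg)
    smoother = None
    denoised = fr.denoised
    if variant == "RTS":
        smoother = filters.rts_smooth(fr, model)
        denoised = smoother.denoised
    return DenoiseResult(denoised=denoised, model=model, filter_result=fr,
                         smoother_result=smoother,
                         order_selection=order_selection)
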