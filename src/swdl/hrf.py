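"""Two-gamma hemodynamic response function and event-train convolution.

The canonical HRF is modelled as the difference of two gamma densities: a
positive response lobe (delay ~6 s) minus a scaled undershoot lobe
(delay ~16 s).  Stimulus regressors are built by convolving an event or
boxcar train sampled on the TR grid with this kernel.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gamma as gamma_dist


@dataclass(frozen=True)
class HrfParams:
    """Parameters of the two-gamma HRF (all time quantities in seconds)."""

    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "response_delay",
            "undershoot_delay",
            "response_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "kernel_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"HrfParams.{name} must be positive")


CANONICAL_HRF = HrfParams()


def hrf_kernel(params: HrfParams = CANONICAL_HRF, tr: float = 1.0) -> np.ndarray:
    """Sample the two-gamma HRF on the TR grid.

    Returns the kernel h[t] = g1(t) - ratio * g2(t) evaluated at
    t = 0, tr, 2*tr, ... up to ``kernel_length``, where g1/g2 are gamma
    densities with shape delay/dispersion and scale dispersion.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, params.kernel_length + 0.5 * tr, tr)
    a1 = params.response_delay / params.response_dispersion
    a2 = params.undershoot_delay / params.undershoot_dispersion
    peak = gamma_dist.pdf(t, a1, scale=params.response_dispersion)
    under = gamma_dist.pdf(t, a2, scale=params.undershoot_dispersion)
    return peak - params.undershoot_ratio * under


def jitter_hrf(
    params: HrfParams, rng: np.random.Generator, sigma: float = 0.5
) -> HrfParams:
    """Perturb delays/dispersions with Gaussian jitter (sd ``sigma`` seconds).

    Values are clipped away from zero so the jittered kernel stays valid.
    Models inter-subject hemodynamic variability.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return params

    def _pos(x: float, lo: float) -> float:
        return max(lo, x + sigma * rng.standard_normal())

    return replace(
        params,
        response_delay=_pos(params.response_delay, 1.0),
        undershoot_delay=_pos(params.undershoot_delay, 2.0),
        response_dispersion=_pos(params.response_dispersion, 0.2),
        undershoot_dispersion=_pos(params.undershoot_dispersion, 0.2),
    )


def convolve_events(
    train: np.ndarray, params: HrfParams = CANONICAL_HRF, tr: float = 1.0
) -> np.ndarray:
    """Convolve a sampled stimulus train with the HRF, truncated to len(train)."""
    train = np.asarray(train, dtype=float)
    kernel = hrf_kernel(params, tr)
    return np.convolve(train, kernel)[: train.size]
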