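"""Diagonal structured state-space (S4D) layer primitives.

A single-direction S4D layer is a bank of H independent single-input
single-output linear state-space systems, each with a diagonal complex state
matrix::

    x'(t) = A x(t) + B u(t),   y(t) = 2 Re(C x(t)) + D u(t)

discretized per channel with a learned timescale Delta = exp(log_dt) under a
zero-order hold.  Because A is diagonal the discrete system is a bank of
scalar recurrences, and the L-step impulse response (the convolution kernel)
has the Vandermonde closed form

    K_l = 2 Re( sum_n C_n Bbar_n Abar_n**l ).

The factor 2 Re(.) accounts for the implicit conjugate-pair modes of a real
system; it can be disabled for scalar closed-form checks.

Both execution paths are exposed: :func:`apply_conv` (kernel + causal
convolution) and :func:`recurrent_scan` (stepwise recurrence).  They are
mathematically identical and serve as mutual oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "S4DLayerParams",
    "init_s4d",
    "discretize_zoh",
    "kernel",
    "apply_conv",
    "recurrent_scan",
]


@dataclass
class S4DLayerParams:
    """Parameters of one S4D layer: H channels x N diagonal modes."""

    A: np.ndarray  # complex [H, N], Re(A) < 0
    B: np.ndarray  # complex [H, N]
    C: np.ndarray  # complex [H, N]
    D: np.ndarray  # real [H]
    log_dt: np.ndarray  # real [H]

    @property
    def channels(self) -> int:
        return self.A.shape[0]

    @property
    def state_size(self) -> int:
        return self.A.shape[1]

    def validate(self) -> None:
        for name in ("A", "B", "C", "D", "log_dt"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr.view(np.float64) if np.iscomplexobj(arr) else arr)):
                raise ValueError(f"S4D parameter {name} contains non-finite values")
        if np.any(self.A.real >= 0):
            raise ValueError("S4D stability requires Re(A) < 0 for every mode")
        if self.A.shape != self.B.shape or self.A.shape != self.C.shape:
            raise ValueError("A, B, C must share the [channels, state_size] shape")


def init_s4d(
    state_size: int,
    channels: int,
    dt_min: float = 1e-3,
    dt_max: float = 1e-1,
    seed: int = 0,
) -> S4DLayerParams:
    """S4D-Lin initialization: A_n = -1/2 + i*pi*n, B = 1, log-uniform dt."""
    if state_size < 1 or channels < 1:
        raise ValueError("state_size and channels must be >= 1")
    if not (0 < dt_min < dt_max):
        raise ValueError("require 0 < dt_min < dt_max")
    rng = np.random.default_rng(seed)
    n = np.arange(state_size)
    A = np.broadcast_to(-0.5 + 1j * np.pi * n, (channels, state_size)).copy()
    B = np.ones((channels, state_size), dtype=complex)
    C = (rng.standard_normal((channels, state_size)) + 1j * rng.standard_normal((channels, state_size))) * (
        0.5 / np.sqrt(state_size)
    )
    D = rng.standard_normal(channels) * 0.1
    log_dt = rng.uniform(np.log(dt_min), np.log(dt_max), size=channels)
    params = S4DLayerParams(A=A, B=B, C=C, D=D, log_dt=log_dt)
    params.validate()
    return params


def discretize_zoh(params: S4DLayerParams) -> tuple[np.ndarray, np.ndarray]:
    """Zero-order-hold discretization: Abar = exp(dt*A), Bbar = (Abar-1)/A * B."""
    params.validate()
    dt = np.exp(params.log_dt)[:, None]
    Abar = np.exp(dt * params.A)
    Bbar = (Abar - 1.0) / params.A * params.B
    return Abar, Bbar


def kernel(params: S4DLayerParams, length: int, real_doubling: bool = True) -> np.ndarray:
    """Real convolution kernel [H, length]: K_l = 2 Re(sum_n C Bbar Abar**l)."""
    if length < 1:
        raise ValueError("kernel length must be >= 1")
    Abar, Bbar = discretize_zoh(params)
    powers = Abar[:, :, None] ** np.arange(length)  # [H, N, L]
    k = np.einsum("hn,hnl->hl", params.C * Bbar, powers)
    return 2.0 * k.real if real_doubling else k.real


def s4d_basis(params: S4DLayerParams, length: int) -> np.ndarray:
    """Complex basis [H, N, L] with basis[h,n,l] = Bbar * Abar**l.

    The kernel is linear in C: K = 2 Re(einsum('hn,hnl->hl', C, basis)).
    Used by the trainable network to differentiate through C only.
    """
    Abar, Bbar = discretize_zoh(params)
    return Bbar[:, :, None] * Abar[:, :, None] ** np.arange(length)


def _check_input(params: S4DLayerParams, u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=np.float64)
    if u.ndim == 2:
        u = u[None]
    if u.ndim != 3 or u.shape[-1] != params.channels:
        raise ValueError(
            f"input must be [L, H] or [B, L, H] with H={params.channels}, got {u.shape}"
        )
    if not np.all(np.isfinite(u)):
        raise ValueError("input contains non-finite values")
    return u


def apply_conv(params: S4DLayerParams, u: np.ndarray, real_doubling: bool = True) -> np.ndarray:
    """Causal convolution path: y_l = sum_{j<=l} K_j u_{l-j} + D u_l."""
    squeeze = np.asarray(u).ndim == 2
    ub = _check_input(params, u)
    _, L, _ = ub.shape
    K = kernel(params, L, real_doubling=real_doubling)
    y = params.D * ub
    for j in range(L):
        y[:, j:, :] += K[:, j] * ub[:, : L - j, :]
    return y[0] if squeeze else y


def recurrent_scan(params: S4DLayerParams, u: np.ndarray, real_doubling: bool = True) -> np.ndarray:
    """Stepwise recurrence path (brute-force oracle for apply_conv)."""
    squeeze = np.asarray(u).ndim == 2
    ub = _check_input(params, u)
    B, L, H = ub.shape
    Abar, Bbar = discretize_zoh(params)
    x = np.zeros((B, H, params.state_size), dtype=complex)
    y = np.empty_like(ub)
    scale = 2.0 if real_doubling else 1.0
    for l in range(L):
        x = Abar * x + Bbar * ub[:, l, :, None]
        y[:, l, :] = scale * np.einsum("hn,bhn->bh", params.C, x).real + params.D * ub[:, l, :]
    return y[0] if squeeze else y
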