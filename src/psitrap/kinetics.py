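"""Analytic kinetic kernels for fluorescence decay analysis.

The building block is an exponential decay convolved with a Gaussian
instrument response, for which a closed form exists:

    f(t) = 1/2 * exp(sigma^2 / (2 tau^2) - (t - mu)/tau)
               * erfc((sigma/tau - (t - mu)/sigma) / sqrt(2))

Evaluated naively the leading exponential overflows whenever sigma/tau is
large (narrow decays under a broad IRF), so the implementation switches to a
scaled-complementary-error-function (erfcx) branch where the erfc argument is
positive.  On top of this kernel the module provides the unbranched
sequential (cascade) compartment populations and the linear map between
evolution-associated spectra (EAS, per-compartment) and decay-associated
spectra (DAS, per-exponential).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import erfc, erfcx

from .types import IRFModel

__all__ = [
    "exp_conv_gauss",
    "bateman_matrix",
    "sequential_profiles",
    "das_from_eas",
    "eas_from_das",
]

_SQRT2 = np.sqrt(2.0)


def exp_conv_gauss(
    t: np.ndarray | float,
    tau: float,
    mu: float = 0.0,
    sigma: float = 0.0,
) -> np.ndarray | float:
    """Exponential decay exp(-t/tau) convolved with a unit-area Gaussian.

    Parameters
    ----------
    t : array-like
        Times (ps).
    tau : float
        Decay lifetime (ps), strictly positive.
    mu, sigma : float
        Center and standard deviation (ps) of the Gaussian IRF. ``sigma=0``
        gives the sharp limit ``exp(-(t-mu)/tau)`` for ``t >= mu`` and zero
        before.

    Returns
    -------
    Intensity with the same shape as ``t``; dimensionless, normalised so the
    sigma -> 0 limit has unit amplitude at ``t = mu``.
    """
    if tau <= 0:
        raise ValueError(f"lifetime must be positive, got {tau}")
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    t = np.asarray(t, dtype=float)
    shifted = t - mu
    if sigma == 0.0:
        out = np.where(shifted >= 0, np.exp(-np.clip(shifted, 0, None) / tau), 0.0)
        return out if out.ndim else float(out)

    x = shifted / sigma
    z = (sigma / tau - x) / _SQRT2
    out = np.empty_like(x)
    pos = z >= 0
    # exp(a)*erfc(z) with a - z^2 = -x^2/2: bounded for z >= 0.
    out[pos] = 0.5 * erfcx(z[pos]) * np.exp(-0.5 * x[pos] ** 2)
    # z < 0 implies the plain exponent is itself negative; no overflow.
    a = sigma**2 / (2 * tau**2) - shifted / tau
    neg = ~pos
    out[neg] = 0.5 * np.exp(a[neg]) * erfc(z[neg])
    return out if out.ndim else float(out)


def _check_distinct(lifetimes: np.ndarray) -> None:
    n = lifetimes.size
    for i in range(n):
        for j in range(i + 1, n):
            scale = max(abs(lifetimes[i]), abs(lifetimes[j]))
            if abs(lifetimes[i] - lifetimes[j]) <= 1e-9 * scale:
                raise ValueError(
                    f"lifetimes {lifetimes[i]} and {lifetimes[j]} coincide within "
                    "1e-9 relative; the cascade solution is degenerate -- perturb "
                    "one of them slightly"
                )


def bateman_matrix(lifetimes: Sequence[float]) -> np.ndarray:
    """Expansion of cascade populations on the exponential basis.

    For the unbranched sequential scheme 1 -> 2 -> ... -> n with unit
    transfer efficiency, compartment *j* evolves as

        c_j(t) = sum_i B[j, i] * exp(-k_i t),   k_i = 1/tau_i,

    and this function returns the lower-triangular matrix ``B`` (the Bateman
    coefficients).  Convolution with the IRF is linear, so the same matrix
    applies to the IRF-convolved exponentials.
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    if lifetimes.size == 0:
        raise ValueError("at least one lifetime required")
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    _check_distinct(lifetimes)
    rates = 1.0 / lifetimes
    n = rates.size
    B = np.zeros((n, n))
    for j in range(n):
        prefactor = np.prod(rates[:j])  # product of upstream transfer rates
        for i in range(j + 1):
            denom = np.prod([rates[l] - rates[i] for l in range(j + 1) if l != i])
            B[j, i] = prefactor / denom if j > 0 else 1.0
    return B


def sequential_profiles(
    lifetimes: Sequence[float],
    t: np.ndarray,
    irf: IRFModel | None = None,
) -> np.ndarray:
    """Populations of the sequential cascade compartments on a time grid.

    Returns an array of shape ``(len(t), n_compartments)``. Compartment 1 is
    the plain IRF-convolved decay of the first lifetime; deeper compartments
    follow the Bateman cascade solution with unit inter-compartment transfer.
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    irf = irf or IRFModel()
    B = bateman_matrix(lifetimes)
    basis = np.column_stack(
        [exp_conv_gauss(t, tau, irf.center, irf.sigma) for tau in lifetimes]
    )
    return basis @ B.T


def das_from_eas(
    eas: np.ndarray | Sequence[Sequence[float]],
    lifetimes: Sequence[float],
) -> np.ndarray:
    """Convert evolution-associated spectra to decay-associated spectra.

    Expanding the cascade populations on the exponential basis,
    ``sum_j EAS_j * c_j(t) = sum_n DAS_n * exp(-k_n t)`` with
    ``DAS = B.T @ EAS``. ``eas`` has shape (n_components, n_wavelengths).
    """
    eas = np.atleast_2d(np.asarray(eas, dtype=float))
    lifetimes = np.asarray(lifetimes, dtype=float)
    if eas.shape[0] != lifetimes.size:
        raise ValueError(
            f"got {eas.shape[0]} spectra for {lifetimes.size} lifetimes"
        )
    return bateman_matrix(lifetimes).T @ eas


def eas_from_das(
    das: np.ndarray | Sequence[Sequence[float]],
    lifetimes: Sequence[float],
) -> np.ndarray:
    """Inverse of :func:`das_from_eas` (triangular solve)."""
    das = np.atleast_2d(np.asarray(das, dtype=float))
    lifetimes = np.asarray(lifetimes, dtype=float)
    if das.shape[0] != lifetimes.size:
        raise ValueError(
            f"got {das.shape[0]} spectra for {lifetimes.size} lifetimes"
        )
    return np.linalg.solve(bateman_matrix(lifetimes).T, das)
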