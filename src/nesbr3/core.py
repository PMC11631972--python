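"""Neutrosophic Burr-III distribution at a fixed indeterminacy endpoint.

The distribution of a positive random variable X with shape parameters
``lam`` (:math:`\\lambda`), ``theta`` (:math:`\\theta`) and indeterminacy
``indet`` (:math:`I \\ge 0`) has CDF

.. math::

    F(x) = \\bigl\\{1 + [(1+I)x]^{-\\theta}\\bigr\\}^{-\\lambda},
    \\qquad \\lambda, \\theta > 0,\\ x > 0,

i.e. a classical Burr-III (Dagum / inverse Burr-XII) variable rescaled by
``1/(1+I)``.  Setting ``indet = 0`` recovers the classical Burr-III
distribution exactly.

A *neutrosophic* quantity is represented as the ordered pair of evaluations
at the two endpoints of the indeterminacy interval ``[I_L, I_N]``; see
:func:`endpoint_params` and :func:`neutro_map`.  No interval arithmetic is
performed — the pair is simply the two classical computations.

All numerical work is done in log space so that extreme shape parameters do
not underflow; the public API is in natural parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import DomainError, HazardOverflowError, ParameterError

__all__ = [
    "IndeterminacyInterval",
    "NesBr3Params",
    "NeutroValue",
    "cdf",
    "log_cdf",
    "pdf",
    "log_pdf",
    "sf",
    "log_sf",
    "hrf",
    "quantile",
    "rvs",
    "endpoint_params",
    "neutro_map",
]


@dataclass(frozen=True)
class IndeterminacyInterval:
    """Indeterminacy interval ``[lower, upper]`` with ``0 <= lower <= upper``.

    ``lower == upper == 0`` recovers classical (crisp) statistics.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        lo, hi = float(self.lower), float(self.upper)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ParameterError("indeterminacy endpoints must be finite")
        if lo < 0 or hi < lo:
            raise ParameterError(
                f"indeterminacy interval requires 0 <= lower <= upper, got [{lo}, {hi}]"
            )
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def is_crisp(self) -> bool:
        return self.lower == 0.0 and self.upper == 0.0

    @property
    def is_degenerate(self) -> bool:
        return self.lower == self.upper

    @property
    def endpoints(self) -> tuple[float, float]:
        return (self.lower, self.upper)


@dataclass(frozen=True)
class NesBr3Params:
    """Shape parameters at one indeterminacy endpoint.

    Parameters
    ----------
    lam, theta : float
        Shape parameters, strictly positive.
    indet : float, optional
        Indeterminacy value ``I >= 0`` at this endpoint (default 0, the
        classical Burr-III case).
    """

    lam: float
    theta: float
    indet: float = 0.0

    def __post_init__(self) -> None:
        lam, theta, indet = float(self.lam), float(self.theta), float(self.indet)
        if not (np.isfinite(lam) and lam > 0):
            raise ParameterError(f"lam must be finite and > 0, got {lam}")
        if not (np.isfinite(theta) and theta > 0):
            raise ParameterError(f"theta must be finite and > 0, got {theta}")
        if not (np.isfinite(indet) and indet >= 0):
            raise ParameterError(f"indet must be finite and >= 0, got {indet}")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "indet", indet)

    @property
    def scale_factor(self) -> float:
        """The factor ``1 + I`` multiplying x inside the CDF kernel."""
        return 1.0 + self.indet


@dataclass(frozen=True)
class NeutroValue:
    """A neutrosophic observation ``[lower, upper]`` with ``0 < lower <= upper``."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        lo, hi = float(self.lower), float(self.upper)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise DomainError("observation endpoints must be finite")
        if lo <= 0:
            raise DomainError(f"observation lower endpoint must be > 0, got {lo}")
        if hi < lo:
            raise DomainError(f"observation upper endpoint {hi} below lower {lo}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    def as_tuple(self) -> tuple[float, float]:
        return (self.lower, self.upper)


def _validate_x(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("x must be finite and strictly positive")
    return arr, scalar


def _maybe_scalar(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def log_cdf(x, p: NesBr3Params):
    """Log of the CDF, stable for extreme shapes."""
    arr, scalar = _validate_x(x)
    t = -p.theta * (np.log(arr) + np.log(p.scale_factor))
    out = -p.lam * np.logaddexp(0.0, t)
    return _maybe_scalar(out, scalar)


def cdf(x, p: NesBr3Params):
    """CDF ``F(x) = {1 + [(1+I)x]^(-theta)}^(-lam)``."""
    arr, scalar = _validate_x(x)
    out = np.exp(log_cdf(arr, p))
    return _maybe_scalar(np.asarray(out), scalar)


def log_pdf(x, p: NesBr3Params):
    """Log-density, computed without under/overflow for extreme shapes."""
    arr, scalar = _validate_x(x)
    lx = np.log(arr)
    ls = np.log(p.scale_factor)
    t = -p.theta * (lx + ls)
    out = (
        np.log(p.lam)
        + np.log(p.theta)
        - p.theta * ls
        - (p.theta + 1.0) * lx
        - (p.lam + 1.0) * np.logaddexp(0.0, t)
    )
    return _maybe_scalar(np.asarray(out), scalar)


def pdf(x, p: NesBr3Params):
    """Density ``f(x) = (1+I)^(-theta) lam theta x^(-theta-1) {1+[(1+I)x]^(-theta)}^(-lam-1)``."""
    arr, scalar = _validate_x(x)
    out = np.exp(log_pdf(arr, p))
    return _maybe_scalar(np.asarray(out), scalar)


def log_sf(x, p: NesBr3Params):
    """Log survival function, accurate in both tails."""
    arr, scalar = _validate_x(x)
    lc = np.asarray(log_cdf(arr, p))
    with np.errstate(divide="ignore"):
        out = np.log(-np.expm1(lc))
    return _maybe_scalar(out, scalar)


def sf(x, p: NesBr3Params):
    """Survival function ``1 - F(x)``, computed as ``-expm1(log F)``."""
    arr, scalar = _validate_x(x)
    out = -np.expm1(np.asarray(log_cdf(arr, p)))
    return _maybe_scalar(out, scalar)


def hrf(x, p: NesBr3Params):
    """Hazard rate ``f(x) / S(x)``.

    Raises
    ------
    HazardOverflowError
        If the survival function is zero to machine precision anywhere on
        ``x`` (the hazard would overflow); callers that want to plot into
        the far right tail should pre-check :func:`sf`.
    """
    arr, scalar = _validate_x(x)
    lsf = np.asarray(log_sf(arr, p))
    if np.any(np.isneginf(lsf)):
        raise HazardOverflowError(
            "survival function underflowed to 0; hazard rate overflows"
        )
    out = np.exp(np.asarray(log_pdf(arr, p)) - lsf)
    return _maybe_scalar(out, scalar)


def quantile(q, p: NesBr3Params):
    """Quantile function, the exact inverse of :func:`cdf`.

    ``x_q = (1+I)^(-1) (q^(-1/lam) - 1)^(-1/theta)`` for ``q`` in (0, 1).
    ``q = 0.5`` yields the median.
    """
    arr = np.asarray(q, dtype=float)
    scalar = arr.ndim == 0
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr >= 1):
        raise DomainError("q must lie strictly inside (0, 1)")
    # q^(-1/lam) - 1 via expm1 for accuracy as q -> 1
    base = np.expm1(-np.log(arr) / p.lam)
    out = np.exp(-np.log(base) / p.theta) / p.scale_factor
    return _maybe_scalar(out, scalar)


def rvs(n: int, p: NesBr3Params, seed) -> np.ndarray:
    """Draw ``n`` variates by inverse-transform sampling.

    ``seed`` may be an int or a :class:`numpy.random.Generator`; the same
    integer seed always reproduces the same sample.
    """
    if int(n) != n or n < 1:
        raise DomainError(f"n must be a positive integer, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(int(n))
    # keep u strictly inside (0, 1)
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return np.asarray(quantile(u, p))


def endpoint_params(
    lam, theta, indet: IndeterminacyInterval
) -> tuple[NesBr3Params, NesBr3Params]:
    """Build the (lower, upper) endpoint parameter pair.

    ``lam`` and ``theta`` may each be a scalar (shared by both endpoints) or
    a ``(lower, upper)`` pair.
    """

    def _pair(v) -> tuple[float, float]:
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            return float(arr), float(arr)
        if arr.shape == (2,):
            return float(arr[0]), float(arr[1])
        raise ParameterError(f"expected a scalar or a pair, got shape {arr.shape}")

    lam_lo, lam_hi = _pair(lam)
    th_lo, th_hi = _pair(theta)
    return (
        NesBr3Params(lam_lo, th_lo, indet.lower),
        NesBr3Params(lam_hi, th_hi, indet.upper),
    )


def neutro_map(
    func: Callable, params: tuple[NesBr3Params, NesBr3Params], *args, **kwargs
) -> tuple:
    """Apply a scalar-endpoint operation to both endpoints, returning a pair.

    This is the whole neutrosophic evaluation contract: an interval-valued
    quantity is the ordered pair ``(func(..., lower), func(..., upper))``.
    """
    return (func(*args, params[0], **kwargs), func(*args, params[1], **kwargs))
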