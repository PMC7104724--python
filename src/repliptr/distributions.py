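"""Circular probability families for coverage-depth modelling.

Bidirectional replication of a circular chromosome makes sequencing depth
peak at the replication origin and trough at the terminus.  Mapping genome
position onto the circle turns the depth profile into a weighted sample of
angles, and the peak-to-trough ratio of a fitted circular density (pPTR)
becomes a growth proxy.  This module provides the six symmetric families
used for that fit, their closed-form pPTR, and the model-free mean
resultant length.

Families and their densities (location mu, angular offset D = theta - mu):

====================  =======================================================  ==================
family                density                                                  pPTR
====================  =======================================================  ==================
von_mises             exp(k cos D) / (2 pi I0(k))                              exp(2 k)
cardioid              (1 + 2 r cos D) / (2 pi)                                 (1+2r)/(1-2r)
wrapped_cauchy        (1 - r^2) / (2 pi (1 + r^2 - 2 r cos D))                 ((1+r)/(1-r))^2
jones_pewsey          (cosh(k psi) + sinh(k psi) cos D)^(1/psi) / C(k, psi)    exp(2 k)
linear_cardioid       (1 + 2 r (||D| - pi| - pi/2)) / (2 pi)                   (1+pi r)/(1-pi r)
exp_linear_cardioid   r exp(2 r (||D| - pi| - pi/2)) / (e^(pi r) - e^(-pi r))  exp(2 pi r)
====================  =======================================================  ==================

The Jones-Pewsey normalization constant is computed by numerical quadrature
of the unnormalized kernel (cached); psi = 0 reduces exactly to the von
Mises case.  The exponential-linear-cardioid exponent groups as
``2 r (||D| - pi| - pi/2)`` which is the grouping under which the printed
normalizer and pPTR are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import integrate, special

from .errors import (
    EmptyInputError,
    InvalidParameterError,
    UnsupportedFamilyError,
)

TWO_PI = 2.0 * math.pi

FAMILIES = (
    "von_mises",
    "cardioid",
    "wrapped_cauchy",
    "jones_pewsey",
    "linear_cardioid",
    "exp_linear_cardioid",
)
EXTENSIONS = ("none", "SE", "InvSE", "MIAE", "InvMIAE")

#: families parameterized by kappa > 0 (the others use rho)
KAPPA_FAMILIES = ("von_mises", "jones_pewsey")

#: open upper bound of the rho parameter per family
RHO_BOUND = {
    "cardioid": 0.5,
    "wrapped_cauchy": 1.0,
    "linear_cardioid": 1.0 / math.pi,
    "exp_linear_cardioid": 1.0 / math.pi,
}

#: margin used to enforce open intervals at parameter-space poles
BOUND_EPS = 1e-8


def wrap_angle(theta):
    """Wrap angle(s) into [0, 2*pi).

    Guards the half-open bound: a tiny negative angle rounds to exactly
    2*pi under fmod and is mapped back to 0.
    """
    w = np.mod(theta, TWO_PI)
    return np.where(w >= TWO_PI, 0.0, w)[()]


@dataclass(frozen=True)
class DistributionSpec:
    """Choice of circular family plus optional shape extension.

    ``SE``/``InvSE`` add one peakedness parameter ``lam``; ``MIAE``/``InvMIAE``
    add one skewness parameter ``nu``.  ``jones_pewsey`` carries the shape
    parameter ``psi`` even unextended.
    """

    family: str
    extension: str = "none"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise UnsupportedFamilyError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.extension not in EXTENSIONS:
            raise InvalidParameterError(
                f"unknown extension {self.extension!r}; expected one of {EXTENSIONS}"
            )

    @property
    def uses_kappa(self) -> bool:
        return self.family in KAPPA_FAMILIES

    @property
    def n_shape_params(self) -> int:
        """Extra shape parameters beyond (mu, concentration)."""
        n = 1 if self.family == "jones_pewsey" else 0
        if self.extension != "none":
            n += 1
        return n


@dataclass(frozen=True)
class ParameterSet:
    """Parameter vector omega of a (possibly extended) circular density.

    Parameters
    ----------
    mu : float
        Location angle in [0, 2*pi); maps to the replication origin.
    concentration : float or ndarray
        kappa (von Mises / Jones-Pewsey) or rho (the other families); one
        value per sample when fitting multi-sample data.
    psi : float
        Jones-Pewsey shape; ignored by other families.
    lam : float
        Peakedness of the SE / InvSE extensions, in (-1, 1).
    nu : float
        Skewness of the MIAE / InvMIAE extensions, in (-1, 1).
    alpha : ndarray or None
        Mixture weights (length M, summing to 1) for multi-origin models.
    """

    mu: float = 0.0
    concentration: float | np.ndarray = 0.0
    psi: float = 0.0
    lam: float = 0.0
    nu: float = 0.0
    alpha: np.ndarray | None = field(default=None)

    def with_(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


def validate_params(spec: DistributionSpec, params: ParameterSet) -> None:
    """Raise :class:`InvalidParameterError` naming any violated bound."""
    conc = np.atleast_1d(np.asarray(params.concentration, dtype=float))
    if spec.uses_kappa:
        if np.any(conc < 0):
            raise InvalidParameterError(
                f"{spec.family}: concentration kappa must be >= 0, got {conc}"
            )
    else:
        bound = RHO_BOUND[spec.family]
        if np.any(conc < 0) or np.any(conc > bound - BOUND_EPS):
            raise InvalidParameterError(
                f"{spec.family}: rho must lie in [0, {bound}) "
                f"(open at the pole, margin {BOUND_EPS}), got {conc}"
            )
    if spec.extension in ("SE", "InvSE") and not abs(params.lam) < 1.0:
        raise InvalidParameterError(
            f"peakedness lam must satisfy |lam| < 1, got {params.lam}"
        )
    if spec.extension in ("MIAE", "InvMIAE") and not abs(params.nu) < 1.0:
        raise InvalidParameterError(
            f"skewness nu must satisfy |nu| < 1, got {params.nu}"
        )
    if params.alpha is not None:
        alpha = np.asarray(params.alpha, dtype=float)
        if np.any(alpha < 0) or abs(alpha.sum() - 1.0) > 1e-8:
            raise InvalidParameterError(
                f"mixture weights alpha must be nonnegative and sum to 1, got {alpha}"
            )


# -- base (vanilla) log-densities -------------------------------------------

@lru_cache(maxsize=512)
def _jp_log_norm(kappa: float, psi: float) -> float:
    """log of the Jones-Pewsey normalization constant, by adaptive quadrature.

    The closed form involves an associated Legendre function; quadrature of
    the kernel avoids its edge cases near psi = 0 and for psi < 0.
    """
    def kernel(d):
        return math.exp(_jp_log_kernel(d, kappa, psi))

    val, _ = integrate.quad(kernel, 0.0, TWO_PI, limit=200)
    return math.log(val)


def _jp_log_kernel(delta, kappa, psi):
    """log of (cosh(k psi) + sinh(k psi) cos(delta))^(1/psi)."""
    x = kappa * psi
    base = np.cosh(x) + np.sinh(x) * np.cos(delta)
    return np.log(base) / psi


def _log_pdf_vanilla(family: str, delta, conc, psi: float = 0.0):
    """Log-density at angular offset delta = theta - mu (any real, wrapped)."""
    delta = wrap_angle(delta)
    if family == "von_mises":
        k = conc
        # log I0 via exponentially scaled Bessel for stability
        return k * np.cos(delta) - math.log(TWO_PI) - (np.log(special.i0e(k)) + k)
    if family == "cardioid":
        return np.log1p(2.0 * conc * np.cos(delta)) - math.log(TWO_PI)
    if family == "wrapped_cauchy":
        r = conc
        return (
            np.log1p(-(r ** 2))
            - math.log(TWO_PI)
            - np.log1p(r ** 2 - 2.0 * r * np.cos(delta))
        )
    if family == "jones_pewsey":
        if abs(psi) < 1e-12:  # exact von Mises limit
            return _log_pdf_vanilla("von_mises", delta, conc)
        return _jp_log_kernel(delta, conc, psi) - _jp_log_norm(float(conc), float(psi))
    if family == "linear_cardioid":
        tri = np.abs(np.abs(delta) - math.pi) - math.pi / 2.0
        return np.log1p(2.0 * conc * tri) - math.log(TWO_PI)
    if family == "exp_linear_cardioid":
        r = conc
        tri = np.abs(np.abs(delta) - math.pi) - math.pi / 2.0
        if r < 1e-12:  # uniform limit
            return np.full_like(np.asarray(tri, dtype=float), -math.log(TWO_PI))
        # normalizer (exp(pi r) - exp(-pi r)) / r, in log space
        log_norm = math.log(math.expm1(2.0 * math.pi * r)) - math.pi * r - math.log(r)
        return 2.0 * r * tri - log_norm
    raise UnsupportedFamilyError(f"unknown family {family!r}")


def log_pdf(spec: DistributionSpec, theta, params: ParameterSet):
    """Log-density of the (possibly extended) family at angle(s) theta.

    ``theta`` may be a scalar or array; the concentration in ``params`` must
    be a scalar here (per-sample handling lives in :mod:`repliptr.model`).
    """
    validate_params(spec, params)
    if spec.extension != "none":
        from . import transforms  # deferred: transforms builds on this module

        return transforms.extended_log_pdf(spec, theta, params)
    delta = np.asarray(theta, dtype=float) - params.mu
    return _log_pdf_vanilla(
        spec.family, delta, float(np.asarray(params.concentration)), params.psi
    )


def pdf(spec: DistributionSpec, theta, params: ParameterSet):
    """Density of the (possibly extended) family at angle(s) theta."""
    return np.exp(log_pdf(spec, theta, params))


# -- pPTR --------------------------------------------------------------------

def pptr(spec: DistributionSpec, params: ParameterSet):
    """Analytic peak-to-trough ratio of the fitted density (pPTR >= 1).

    Closed forms per family (see module docstring).  Invariant to the
    skewness parameter of the InvMIAE extension by construction.
    """
    validate_params(spec, params)
    conc = np.asarray(params.concentration, dtype=float)
    fam = spec.family
    if fam in ("von_mises", "jones_pewsey"):
        out = np.exp(2.0 * conc)
    elif fam == "cardioid":
        out = (1.0 + 2.0 * conc) / (1.0 - 2.0 * conc)
    elif fam == "wrapped_cauchy":
        out = ((1.0 + conc) / (1.0 - conc)) ** 2
    elif fam == "linear_cardioid":
        out = (1.0 + math.pi * conc) / (1.0 - math.pi * conc)
    elif fam == "exp_linear_cardioid":
        out = np.exp(2.0 * math.pi * conc)
    else:  # pragma: no cover
        raise UnsupportedFamilyError(fam)
    return out if out.ndim else float(out)


def concentration_for_pptr(spec: DistributionSpec, target_pptr: float) -> float:
    """Concentration (kappa or rho) whose analytic pPTR equals ``target_pptr``.

    The algebraic inverse of the pPTR column; used for prior calibration and
    simulation fixtures.  Raises when the target is unreachable within the
    family's concentration bound (e.g. the exponential linear cardioid caps
    at pPTR = e^2).
    """
    r = float(target_pptr)
    if r < 1.0:
        raise InvalidParameterError(f"target pPTR must be >= 1, got {r}")
    fam = spec.family
    if fam in ("von_mises", "jones_pewsey"):
        conc = math.log(r) / 2.0
    elif fam == "cardioid":
        conc = (r - 1.0) / (2.0 * (r + 1.0))
    elif fam == "wrapped_cauchy":
        s = math.sqrt(r)
        conc = (s - 1.0) / (s + 1.0)
    elif fam == "linear_cardioid":
        conc = (r - 1.0) / (math.pi * (r + 1.0))
    elif fam == "exp_linear_cardioid":
        conc = math.log(r) / (2.0 * math.pi)
    else:
        raise UnsupportedFamilyError(fam)
    if not spec.uses_kappa and conc > RHO_BOUND[fam] - BOUND_EPS:
        raise InvalidParameterError(
            f"{fam}: pPTR {r} requires rho {conc:.4g}, beyond the bound "
            f"{RHO_BOUND[fam]:.4g}"
        )
    return conc


def rho_from_kappa(family: str, kappa: float) -> float:
    """Map a von Mises kappa onto the matched rho of a rho-family.

    rho_c = tanh(kappa)/2 (cardioid) and rho_wC = tanh(kappa/2)
    (wrapped Cauchy); other families have no such alignment.
    """
    if kappa < 0:
        raise InvalidParameterError(f"kappa must be >= 0, got {kappa}")
    if family == "cardioid":
        return math.tanh(kappa) / 2.0
    if family == "wrapped_cauchy":
        return math.tanh(kappa / 2.0)
    raise UnsupportedFamilyError(
        f"rho_from_kappa is defined for cardioid and wrapped_cauchy only, got {family!r}"
    )


def mean_resultant_length(angles, weights=None) -> float:
    """Weighted mean resultant length in [0, 1].

    Weights act as repetition counts (stacked depth observations); ``None``
    means unit weights.
    """
    angles = np.asarray(angles, dtype=float)
    w = np.ones_like(angles) if weights is None else np.asarray(weights, dtype=float)
    total = w.sum()
    if total < 1:
        raise EmptyInputError("mean resultant length needs total weight >= 1")
    c = float(np.sum(w * np.cos(angles)))
    s = float(np.sum(w * np.sin(angles)))
    return math.sqrt(c * c + s * s) / total
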