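"""Shape extensions of the circular families and shared numerical kernels.

Two pairs of argument transformations reshape a symmetric base density
f0 (written here in mode-centered coordinates x = theta - mu):

* peakedness (Batschelet) —
  SE:     f(x) proportional to f0(x + lam*sin x), renormalized numerically;
  InvSE:  f(x) = f0(g(x)) * g'(x) with
          g(x) = (1-lam)/(1+lam)*x + 2*lam/(1+lam)*t^{-1}(x),
          t(y) = y - (1+lam)/2 * sin y.
          This is the change-of-variables density of a base draw pushed
          through g^{-1} (the inverse-Batschelet construction), so the
          normalization constant is unchanged — no quadrature is needed.
* mode-invariant skewness —
  MIAE:    f(x) proportional to f0(x - nu*sin^2(x)), renormalized;
  InvMIAE: f(x) = f0(s^{-1}(x)) with s(y) = y + nu*sin^2(y); normalization,
           mode location and peak-to-trough ratio are all unchanged.
  Both skew maps are strictly increasing for |nu| < 1, preserve the mode at
  mu exactly, and mirror into their own nu -> -nu counterparts.

Numerical kernels follow fixed conventions: composite Simpson quadrature
with 20 subintervals for renormalization, and Newton (|parameter| < 0.8,
tolerance = single-precision machine epsilon on |f|, 30 iterations) or
Illinois (otherwise, tolerance 1e-13, 100 iterations) root-finding for the
inverse transforms.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from . import distributions as dist
from .errors import InvalidParameterError, NonConvergenceError

TWO_PI = 2.0 * math.pi

#: |f| tolerance for Newton's method: single-precision machine epsilon
NEWTON_TOL = float(np.finfo(np.float32).eps)
NEWTON_MAXITER = 30
ILLINOIS_TOL = 1.0e-13
ILLINOIS_MAXITER = 100
#: |lam| / |nu| threshold at which root-finding switches Newton -> Illinois
ROOTFIND_SWITCH = 0.8
#: Simpson subinterval count used for density renormalization
SIMPSON_N = 20


# -- quadrature --------------------------------------------------------------

def simpson_integrate(f, n_subintervals: int = SIMPSON_N, a: float = 0.0,
                      b: float = TWO_PI) -> float:
    """Composite Simpson estimate of the integral of ``f`` over [a, b].

    ``f`` must accept an ndarray of abscissae.  ``n_subintervals`` must be
    even (each Simpson panel spans two subintervals).
    """
    n = int(n_subintervals)
    if n < 2 or n % 2:
        raise ValueError(f"n_subintervals must be even and >= 2, got {n}")
    x = np.linspace(a, b, n + 1)
    y = np.asarray(f(x), dtype=float)
    h = (b - a) / n
    return float(h / 3.0 * (y[0] + y[-1] + 4.0 * y[1:-1:2].sum() + 2.0 * y[2:-1:2].sum()))


# -- root finding ------------------------------------------------------------

def newton(f, x0: float, fprime=None, tol: float = NEWTON_TOL,
           maxiter: int = NEWTON_MAXITER) -> float:
    """Newton's method on a scalar function; converges when |f(x)| < tol."""
    x = float(x0)
    h = 1e-7
    for _ in range(maxiter):
        fx = f(x)
        if abs(fx) < tol:
            return x
        d = fprime(x) if fprime is not None else (f(x + h) - f(x - h)) / (2 * h)
        if d == 0:
            break
        x -= fx / d
    if abs(f(x)) < tol:
        return x
    raise NonConvergenceError(
        f"Newton's method did not reach |f| < {tol} in {maxiter} iterations",
        last_iterate=x,
    )


def illinois(f, a: float, b: float, tol: float = ILLINOIS_TOL,
             maxiter: int = ILLINOIS_MAXITER) -> float:
    """Illinois-modified regula falsi on a sign-changing bracket [a, b]."""
    fa, fb = f(a), f(b)
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if np.sign(fa) == np.sign(fb):
        raise ValueError(
            f"illinois: f has the same sign at both bracket endpoints "
            f"({a}: {fa}, {b}: {fb})"
        )
    side = 0
    x = a
    for _ in range(maxiter):
        x = b - fb * (b - a) / (fb - fa)
        fx = f(x)
        if abs(fx) < tol:
            return x
        if np.sign(fx) == np.sign(fb):
            b, fb = x, fx
            if side == -1:
                fa *= 0.5  # Illinois trick: damp the stagnant endpoint
            side = -1
        else:
            a, fa = x, fx
            if side == 1:
                fb *= 0.5
            side = 1
    raise NonConvergenceError(
        f"Illinois method did not reach |f| < {tol} in {maxiter} iterations",
        last_iterate=x,
    )


def root_find(f, x0_or_bracket, method: str, fprime=None) -> float:
    """Dispatch to :func:`newton` (initial guess) or :func:`illinois` (bracket)."""
    if method == "newton":
        return newton(f, x0_or_bracket, fprime=fprime)
    if method == "illinois":
        a, b = x0_or_bracket
        return illinois(f, a, b)
    raise ValueError(f"unknown root-finding method {method!r}")


# -- forward transforms (mode-centered coordinates) --------------------------

def centered(theta, mu):
    """Map angles to mode-centered offsets in (-pi, pi]."""
    return np.pi - np.mod(np.pi - (np.asarray(theta, dtype=float) - mu), TWO_PI)


def se_transform(theta, mu: float, lam: float):
    """Batschelet argument g_lam(theta) = (theta-mu) + lam*sin(theta-mu)."""
    _check_extra(lam, "lam")
    x = centered(theta, mu)
    return x + lam * np.sin(x)


def t1_lam(x, lam: float):
    """t_{1,lam}(x) = x - (1+lam)/2 * sin x (mode-centered)."""
    return x - 0.5 * (1.0 + lam) * np.sin(x)


def _invert_increasing(func, dfunc, targets, param: float):
    """Pointwise inverse of a strictly increasing circle map y -> func(y).

    Newton from the target itself for |param| < 0.8, else Illinois on the
    bracket [target - pi, target + pi] (valid because |func(y) - y| < pi/2
    for the admissible parameter range, so the bracket always sign-changes).
    """
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    out = np.empty_like(targets)
    if abs(param) < ROOTFIND_SWITCH:
        # vectorized Newton: same scheme as the scalar kernel, run in parallel
        y = targets.copy()
        for _ in range(NEWTON_MAXITER):
            fy = func(y) - targets
            if np.all(np.abs(fy) < NEWTON_TOL):
                break
            y = y - fy / dfunc(y)
        fy = func(y) - targets
        if not np.all(np.abs(fy) < NEWTON_TOL):
            bad = float(y[np.argmax(np.abs(fy))])
            raise NonConvergenceError(
                "Newton inverse transform failed to converge", last_iterate=bad
            )
        out[:] = y
    else:
        for j, tgt in enumerate(targets):
            out[j] = illinois(lambda y: func(y) - tgt, tgt - math.pi, tgt + math.pi)
    return out


def invse_transform(theta, mu: float, lam: float, with_jacobian: bool = False):
    """Inverse-Batschelet argument; identity at lam = 0.

    g(x) = (1-lam)/(1+lam)*x + 2*lam/(1+lam) * t_{1,lam}^{-1}(x) on
    mode-centered x.  With ``with_jacobian=True`` also returns g'(x), the
    factor that makes f0(g(x)) * g'(x) a probability density without
    renormalization.
    """
    _check_extra(lam, "lam")
    x = centered(theta, mu)
    if lam == 0.0:
        ones = np.ones_like(np.asarray(x, dtype=float))
        return (x, ones) if with_jacobian else x
    tinv = _invert_increasing(
        lambda y: t1_lam(y, lam),
        lambda y: 1.0 - 0.5 * (1.0 + lam) * np.cos(y),
        x,
        lam,
    )
    a = (1.0 - lam) / (1.0 + lam)
    b = 2.0 * lam / (1.0 + lam)
    g = a * x + b * tinv
    if not with_jacobian:
        return g
    # (t^{-1})'(x) = 1 / t'(t^{-1}(x)); t' >= (1-lam)/2 > 0 for |lam| < 1
    dtinv = 1.0 / (1.0 - 0.5 * (1.0 + lam) * np.cos(tinv))
    return g, a + b * dtinv


def miae_transform(theta, mu: float, nu: float):
    """Mode-invariant skew argument g_nu(theta) = (theta-mu) - nu*sin^2(theta-mu)."""
    _check_extra(nu, "nu")
    x = centered(theta, mu)
    return x - nu * np.sin(x) ** 2


def s_nu(x, nu: float):
    """s_nu(x) = x + nu*sin^2(x); strictly increasing for |nu| < 1."""
    return x + nu * np.sin(x) ** 2


def invmiae_transform(theta, mu: float, nu: float):
    """Inverse mode-invariant skew argument s_nu^{-1}(theta - mu)."""
    _check_extra(nu, "nu")
    x = centered(theta, mu)
    if nu == 0.0:
        return x
    return _invert_increasing(
        lambda y: s_nu(y, nu),
        lambda y: 1.0 + nu * np.sin(2.0 * y),
        x,
        nu,
    )


def _check_extra(value: float, name: str) -> None:
    if not abs(value) < 1.0:
        raise InvalidParameterError(f"|{name}| must be < 1, got {value}")


# -- extended densities ------------------------------------------------------

def _base0_log_pdf(spec, params, x):
    """Vanilla log-density of the base family at mode-centered offsets x."""
    return dist._log_pdf_vanilla(
        spec.family, x, float(np.asarray(params.concentration)), params.psi
    )


@lru_cache(maxsize=512)
def _log_norm_const(family: str, conc: float, psi: float, extension: str,
                    extra: float) -> float:
    """log normalization constant of an SE or MIAE density (Simpson, n=20)."""
    spec = dist.DistributionSpec(family)
    params = dist.ParameterSet(mu=0.0, concentration=conc, psi=psi)

    if extension == "SE":
        def f(x):
            return np.exp(_base0_log_pdf(spec, params, x + extra * np.sin(x)))
    else:  # MIAE
        def f(x):
            return np.exp(_base0_log_pdf(spec, params, x - extra * np.sin(x) ** 2))

    return math.log(simpson_integrate(f, SIMPSON_N))


def extended_log_pdf(spec, theta, params):
    """Log-density of an SE/InvSE/MIAE/InvMIAE-extended family at theta.

    SE and MIAE are renormalized with Simpson(20); InvSE and InvMIAE keep
    the base normalization constant by construction.
    """
    ext = spec.extension
    conc = float(np.asarray(params.concentration))
    scalar_in = np.ndim(theta) == 0
    extra = params.lam if ext in ("SE", "InvSE") else params.nu
    if extra == 0.0:  # exact base density (no quadrature round-off)
        out = _base0_log_pdf(spec, params, centered(theta, params.mu))
        return float(out) if scalar_in and np.ndim(out) else out
    if ext == "SE":
        arg = se_transform(theta, params.mu, params.lam)
        out = _base0_log_pdf(spec, params, arg) - _log_norm_const(
            spec.family, conc, float(np.asarray(params.psi)), "SE", params.lam
        )
    elif ext == "InvSE":
        arg, jac = invse_transform(theta, params.mu, params.lam, with_jacobian=True)
        out = _base0_log_pdf(spec, params, arg) + np.log(jac)
    elif ext == "MIAE":
        arg = miae_transform(theta, params.mu, params.nu)
        out = _base0_log_pdf(spec, params, arg) - _log_norm_const(
            spec.family, conc, float(np.asarray(params.psi)), "MIAE", params.nu
        )
    elif ext == "InvMIAE":
        arg = invmiae_transform(theta, params.mu, params.nu)
        out = _base0_log_pdf(spec, params, arg)
    else:
        raise InvalidParameterError(f"unknown extension {ext!r}")
    if scalar_in:
        return float(np.asarray(out).reshape(-1)[0])
    return np.asarray(out).reshape(np.shape(theta))
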