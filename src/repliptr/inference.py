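"""Parameter estimation and model selection.

Two estimation modes are provided:

* optimizing — maximize the joint posterior (likelihood x priors) with
  L-BFGS over an unconstrained reparameterization, restarting from
  ``n_seeds`` seeded initial points and keeping the run with the highest
  posterior density (defaults: 1 restart for single-origin models, 30 for
  mixtures);
* sampling — ensemble MCMC (emcee's affine-invariant sampler) over the
  same unconstrained space, reporting the expected a posteriori (EAP)
  estimate over post-warmup draws.  Convergence is checked with split-Rhat
  per parameter and a fit is accepted only when every Rhat <= 1.1.

Unconstrained reparameterization: the location is a 2-vector mapped through
atan2 (so cyclicity never traps the optimizer at the 0/2*pi seam);
kappa = exp(z); rho = bound * logistic(z); psi is unconstrained; lam and nu
are tanh(z); mixture weights are a softmax with the last logit pinned to 0.

Model choice uses AIC = 2k - 2logL, BIC = k log(sum_s T_s) - 2logL, WAIC
from pointwise log-likelihood draws (sampling mode), and Wilks' chi-squared
likelihood-ratio test for nested pairs.  Parameter counts: 1 + S for
vanilla non-Jones-Pewsey models, 1 + 2S for Jones-Pewsey (per-sample shape),
+1 for a peakedness/skewness extension, and M + M*S + (M-1) for an M-origin
mixture.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .distributions import RHO_BOUND, DistributionSpec, ParameterSet
from .errors import FitFailureError
from .model import (
    CoverageTrack,
    MixtureParameterSet,
    PriorSpec,
    _as_track_list,
    log_prior,
    loglik_mixture,
    loglik_single,
    pptr_per_sample,
    reparam_location,
    wptr_and_mwptr,
)

RHAT_ACCEPT = 1.1

#: paper-style sampler defaults (steps, warmup): single origin and mixture
MCMC_DEFAULT_SINGLE = (500, 300)
MCMC_DEFAULT_MIXTURE = (1500, 1000)


# -- unconstrained <-> constrained packing -----------------------------------

class _Packer:
    """Maps between an unconstrained vector and model parameters."""

    def __init__(self, spec: DistributionSpec, S: int, M: int = 1):
        self.spec = spec
        self.S = S
        self.M = M
        if M > 1 and spec.family != "von_mises":
            raise ValueError("mixture models use the von Mises family")
        per_sample_shape = S if spec.family == "jones_pewsey" else 0
        extension = 1 if spec.extension != "none" else 0
        if M == 1:
            self.ndim = 2 + S + per_sample_shape + extension
        else:
            self.ndim = 2 * M + M * S + (M - 1)

    def _conc(self, z):
        if self.spec.uses_kappa:
            return np.exp(np.clip(z, -30.0, 10.0))
        bound = RHO_BOUND[self.spec.family]
        return (bound - 1e-8) * special.expit(z)

    def unpack(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        if self.M == 1:
            mu = reparam_location(x[0:2])
            conc = self._conc(x[2:2 + self.S])
            pos = 2 + self.S
            psi = 0.0
            if self.spec.family == "jones_pewsey":
                psi = x[pos:pos + self.S].copy()
                pos += self.S
            lam = nu = 0.0
            if self.spec.extension in ("SE", "InvSE"):
                lam = float(np.tanh(x[pos]))
            elif self.spec.extension in ("MIAE", "InvMIAE"):
                nu = float(np.tanh(x[pos]))
            return ParameterSet(mu=mu, concentration=conc, psi=psi, lam=lam, nu=nu)
        M, S = self.M, self.S
        mus = np.array([
            reparam_location(x[2 * m:2 * m + 2]) for m in range(M)
        ])
        conc = self._conc(x[2 * M:2 * M + M * S]).reshape(M, S)
        logits = np.concatenate([x[2 * M + M * S:], [0.0]])
        alpha = special.softmax(logits)
        return MixtureParameterSet(mus, conc, alpha)

    def random_init(self, rng: np.random.Generator) -> np.ndarray:
        x = np.empty(self.ndim)
        if self.M == 1:
            ang = rng.uniform(0, 2 * math.pi)
            x[0:2] = (math.cos(ang), math.sin(ang))
            x[2:2 + self.S] = rng.normal(-1.5, 1.0, self.S)
            x[2 + self.S:] = rng.normal(0.0, 0.3, self.ndim - 2 - self.S)
        else:
            for m in range(self.M):
                ang = rng.uniform(0, 2 * math.pi)
                x[2 * m:2 * m + 2] = (math.cos(ang), math.sin(ang))
            x[2 * self.M:2 * self.M + self.M * self.S] = rng.normal(
                0.0, 1.0, self.M * self.S
            )
            x[2 * self.M + self.M * self.S:] = rng.normal(
                0.0, 0.1, self.M - 1
            )
        return x


# -- results -----------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a single- or multi-origin model fit."""

    mode: str  # "optimizing" | "sampling"
    spec: DistributionSpec
    params: ParameterSet | MixtureParameterSet
    loglik: float
    logpost: float
    pptr: np.ndarray  # per-sample (single-origin) or unweighted per-component
    seed: int
    wptr: np.ndarray | None = None  # (M, S), mixtures
    mwptr: np.ndarray | None = None  # (S,), mixtures
    rhat: dict | None = None
    accepted: bool = True
    n_draws: int = 0
    draws: np.ndarray | None = None  # post-warmup unconstrained draws (n, ndim)
    packer: _Packer | None = None
    ic: dict = field(default_factory=dict)

    @property
    def is_mixture(self) -> bool:
        return isinstance(self.params, MixtureParameterSet)

    def to_dict(self) -> dict:
        p = self.params
        if self.is_mixture:
            par = {
                "mus": p.mus.tolist(),
                "concentrations": p.concentrations.tolist(),
                "alpha": p.alpha.tolist(),
            }
        else:
            par = {
                "mu": float(p.mu),
                "concentration": np.atleast_1d(p.concentration).tolist(),
                "psi": np.atleast_1d(p.psi).tolist(),
                "lam": float(p.lam),
                "nu": float(p.nu),
            }
        out = {
            "mode": self.mode,
            "family": self.spec.family,
            "extension": self.spec.extension,
            "params": par,
            "loglik": float(self.loglik),
            "pptr": np.atleast_1d(self.pptr).tolist(),
            "seed": int(self.seed),
            "accepted": bool(self.accepted),
            "ic": {k: float(v) for k, v in self.ic.items()},
        }
        if self.wptr is not None:
            out["wptr"] = np.asarray(self.wptr).tolist()
            out["mwptr"] = np.asarray(self.mwptr).tolist()
        if self.rhat is not None:
            out["rhat"] = {k: float(v) for k, v in self.rhat.items()}
        return out


@dataclass
class ICReport:
    """Information criteria of one fitted model."""

    label: str
    k_params: int
    loglik: float
    aic: float
    bic: float
    waic: float | None = None
    lr_pvalue: float | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "k_params": self.k_params,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "waic": self.waic,
            "lr_pvalue": self.lr_pvalue,
        }


def k_parameters(spec: DistributionSpec, S: int, M: int = 1) -> int:
    """Free-parameter count used by AIC/BIC (see module docstring)."""
    if M > 1:
        return M + M * S + (M - 1)
    k = 1 + S
    if spec.family == "jones_pewsey":
        k += S
    if spec.extension != "none":
        k += 1
    return k


# -- objective ---------------------------------------------------------------

def _make_logpost(tracks, spec, priors, packer):
    # standard-normal regularizer on the location 2-vector components: the
    # vector's radius is non-identified (only atan2 matters), and this term
    # pins it near 1 without altering the location's marginal posterior
    n_loc = 2 * packer.M

    def logpost(x):
        try:
            params = packer.unpack(x)
            if packer.M == 1:
                ll = loglik_single(tracks, spec, params)
            else:
                ll = loglik_mixture(tracks, spec, params)
            lp = log_prior(spec, params, priors)
        except (ValueError, FloatingPointError, OverflowError):
            return -np.inf
        out = ll + lp - 0.5 * float(np.dot(x[:n_loc], x[:n_loc]))
        return out if np.isfinite(out) else -np.inf

    return logpost


def _finalize(mode, spec, params, tracks, priors, seed, packer, logpost_val,
              **extra) -> FitResult:
    if isinstance(params, MixtureParameterSet):
        params = params.sorted_by_mu()
        ll = loglik_mixture(tracks, spec, params)
        wptr, mwptr = wptr_and_mwptr(spec, params)
        ptr = np.exp(2.0 * params.concentrations).mean(axis=1)  # unweighted, per comp.
        return FitResult(
            mode=mode, spec=spec, params=params, loglik=ll,
            logpost=logpost_val, pptr=ptr, wptr=wptr, mwptr=mwptr, seed=seed,
            packer=packer, **extra,
        )
    ll = loglik_single(tracks, spec, params)
    return FitResult(
        mode=mode, spec=spec, params=params, loglik=ll, logpost=logpost_val,
        pptr=pptr_per_sample(spec, params), seed=seed, packer=packer, **extra,
    )


# -- MAP ---------------------------------------------------------------------

def fit_map(tracks, spec: DistributionSpec, priors: PriorSpec = PriorSpec(),
            n_seeds: int | None = None, seed: int = 0, M: int = 1) -> FitResult:
    """Maximum a posteriori fit with seeded multi-start L-BFGS.

    Restart seeds are ``seed + 0 .. n_seeds-1``; the restart with the
    highest posterior density wins, making the result deterministic given
    ``seed``.
    """
    tracks = _as_track_list(tracks)
    S = len(tracks)
    if n_seeds is None:
        if M > 1:
            n_seeds = 30
        elif spec.n_shape_params > 0:
            # shape-extended likelihood surfaces are multimodal in psi/lam/nu
            n_seeds = 5
        else:
            n_seeds = 1
    packer = _Packer(spec, S, M)
    logpost = _make_logpost(tracks, spec, priors, packer)

    best_x, best_val = None, -np.inf
    failures = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        x0 = packer.random_init(rng)
        try:
            res = optimize.minimize(
                lambda x: -logpost(x), x0, method="L-BFGS-B",
                options={"maxiter": 500},
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if np.isfinite(res.fun) and -res.fun > best_val:
            best_val, best_x = -res.fun, res.x
    if best_x is None:
        raise FitFailureError(
            f"all {n_seeds} optimizer restarts failed: {failures[:3]}"
        )
    params = packer.unpack(best_x)
    return _finalize("optimizing", spec, params, tracks, priors, seed, packer,
                     best_val)


# -- MCMC --------------------------------------------------------------------

def _circular_mean(angles: np.ndarray) -> float:
    return float(np.mod(
        math.atan2(np.sin(angles).mean(), np.cos(angles).mean()), 2 * math.pi
    ))


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain rank-normalized Rhat (chains on axis 0, split in halves).

    A constant chain has Rhat 1 by convention (no between/within variance).
    """
    import arviz as az

    x = np.atleast_2d(np.asarray(x, dtype=float))
    if np.ptp(x) == 0.0:
        return 1.0
    n = x.shape[1] // 2 * 2
    halves = x[:, :n].reshape(x.shape[0] * 2, n // 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(halves))


def fit_mcmc(tracks, spec: DistributionSpec, priors: PriorSpec = PriorSpec(),
             chains: int = 1, iterations: int | None = None,
             warmup: int | None = None, seed: int = 0, M: int = 1,
             init: FitResult | None = None) -> FitResult:
    """Posterior sampling with the affine-invariant ensemble sampler.

    ``iterations`` counts ensemble steps; defaults are 500 steps with a
    300-step warm-up for single-origin models and 1500/1000 for mixtures.
    The walkers of each requested chain are initialized in a tight ball
    around a MAP fit.  The EAP over post-warmup draws is reported, with
    split-Rhat computed across walkers; the fit is flagged ``accepted``
    only if every Rhat <= 1.1.
    """
    import emcee

    tracks = _as_track_list(tracks)
    S = len(tracks)
    if iterations is None or warmup is None:
        it, wu = MCMC_DEFAULT_MIXTURE if M > 1 else MCMC_DEFAULT_SINGLE
        iterations = iterations if iterations is not None else it
        warmup = warmup if warmup is not None else wu
    packer = _Packer(spec, S, M)
    logpost = _make_logpost(tracks, spec, priors, packer)

    if init is None:
        init = fit_map(tracks, spec, priors, seed=seed, M=M,
                       n_seeds=30 if M > 1 else 1)
    # re-pack the MAP estimate as the walker-ball center
    x_map = _pack_params(packer, init.params)

    nwalkers = max(4 * packer.ndim, 16)
    nwalkers += nwalkers % 2
    rng = np.random.default_rng(seed)
    all_draws = []
    for c in range(chains):
        p0 = x_map + 5e-2 * rng.standard_normal((nwalkers, packer.ndim))
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(nwalkers, packer.ndim, logpost, moves=moves)
        sampler.random_state = np.random.RandomState(seed + 1000 * c + 1).get_state()
        sampler.run_mcmc(p0, iterations, progress=False)
        all_draws.append(sampler.get_chain(discard=warmup))  # (steps, walkers, ndim)
    chain = np.concatenate(all_draws, axis=1)  # walkers pooled across chains

    nsteps, nwalk, ndim = chain.shape
    flat = chain.reshape(-1, ndim)

    # constrained draws for EAP; Rhat treats each requested chain's ensemble,
    # flattened step-major, as one chain and splits it in halves
    named = _constrained_named_draws(packer, chain)
    per_chain = [_constrained_named_draws(packer, ch) for ch in all_draws]
    rhat = {
        k: _split_rhat(np.stack([pc[k].reshape(-1) for pc in per_chain]))
        for k in named
    }
    accepted = all(v <= RHAT_ACCEPT for v in rhat.values())

    params = _eap_params(packer, named)
    fit = _finalize(
        "sampling", spec, params, tracks, priors, seed, packer,
        float(np.mean([logpost(x) for x in flat[:: max(1, len(flat) // 50)]])),
        rhat=rhat, accepted=accepted, n_draws=int(flat.shape[0]), draws=flat,
    )
    return fit


def _pack_params(packer: _Packer, params) -> np.ndarray:
    """Inverse of :meth:`_Packer.unpack` (used to seed walkers at the MAP)."""
    spec = packer.spec
    x = np.empty(packer.ndim)

    def conc_inv(c):
        c = np.asarray(c, dtype=float)
        if spec.uses_kappa:
            return np.log(np.clip(c, 1e-12, None))
        bound = RHO_BOUND[spec.family]
        p = np.clip(c / (bound - 1e-8), 1e-12, 1 - 1e-12)
        return special.logit(p)

    if packer.M == 1:
        x[0] = math.cos(params.mu)
        x[1] = math.sin(params.mu)
        conc = np.atleast_1d(np.asarray(params.concentration, dtype=float))
        if conc.size == 1 and packer.S > 1:
            conc = np.repeat(conc, packer.S)
        x[2:2 + packer.S] = conc_inv(conc)
        pos = 2 + packer.S
        if spec.family == "jones_pewsey":
            psi = np.atleast_1d(np.asarray(params.psi, dtype=float))
            if psi.size == 1 and packer.S > 1:
                psi = np.repeat(psi, packer.S)
            x[pos:pos + packer.S] = psi
            pos += packer.S
        if spec.extension in ("SE", "InvSE"):
            x[pos] = np.arctanh(np.clip(params.lam, -1 + 1e-9, 1 - 1e-9))
        elif spec.extension in ("MIAE", "InvMIAE"):
            x[pos] = np.arctanh(np.clip(params.nu, -1 + 1e-9, 1 - 1e-9))
    else:
        M, S = packer.M, packer.S
        for m in range(M):
            x[2 * m] = math.cos(params.mus[m])
            x[2 * m + 1] = math.sin(params.mus[m])
        x[2 * M:2 * M + M * S] = conc_inv(params.concentrations.ravel())
        la = np.log(np.clip(params.alpha, 1e-12, None))
        x[2 * M + M * S:] = la[:-1] - la[-1]
    return x


def _constrained_named_draws(packer: _Packer, chain: np.ndarray) -> dict:
    """Per-parameter constrained draws, shaped (steps, walkers)."""
    nsteps, nwalk, _ = chain.shape
    out: dict[str, np.ndarray] = {}

    def store(name, arr):
        out[name] = np.asarray(arr).reshape(nsteps, nwalk)

    spec, M, S = packer.spec, packer.M, packer.S
    if M == 1:
        mu = np.arctan2(chain[..., 1], chain[..., 0]) % (2 * math.pi)
        store("mu", mu)
        for s in range(S):
            store(f"concentration[{s}]", packer._conc(chain[..., 2 + s]))
        pos = 2 + S
        if spec.family == "jones_pewsey":
            for s in range(S):
                store(f"psi[{s}]", chain[..., pos + s])
            pos += S
        if spec.extension in ("SE", "InvSE"):
            store("lam", np.tanh(chain[..., pos]))
        elif spec.extension in ("MIAE", "InvMIAE"):
            store("nu", np.tanh(chain[..., pos]))
        return out
    for m in range(M):
        mu = np.arctan2(chain[..., 2 * m + 1], chain[..., 2 * m]) % (2 * math.pi)
        store(f"mu[{m}]", mu)
    for m in range(M):
        for s in range(S):
            store(f"concentration[{m},{s}]",
                  packer._conc(chain[..., 2 * M + m * S + s]))
    logits = np.concatenate(
        [chain[..., 2 * M + M * S:], np.zeros(chain.shape[:2] + (1,))], axis=-1
    )
    alpha = special.softmax(logits, axis=-1)
    for m in range(M):
        store(f"alpha[{m}]", alpha[..., m])
    return out


def _eap_params(packer: _Packer, named: dict):
    """Expected-a-posteriori parameters (circular mean for locations)."""
    spec, M, S = packer.spec, packer.M, packer.S
    if M == 1:
        conc = np.array([named[f"concentration[{s}]"].mean() for s in range(S)])
        kw = dict(mu=_circular_mean(named["mu"].ravel()), concentration=conc)
        if spec.family == "jones_pewsey":
            kw["psi"] = np.array([named[f"psi[{s}]"].mean() for s in range(S)])
        if spec.extension in ("SE", "InvSE"):
            kw["lam"] = float(named["lam"].mean())
        if spec.extension in ("MIAE", "InvMIAE"):
            kw["nu"] = float(named["nu"].mean())
        return ParameterSet(**kw)
    mus = np.array([_circular_mean(named[f"mu[{m}]"].ravel()) for m in range(M)])
    conc = np.array([
        [named[f"concentration[{m},{s}]"].mean() for s in range(S)]
        for m in range(M)
    ])
    alpha = np.array([named[f"alpha[{m}]"].mean() for m in range(M)])
    alpha = alpha / alpha.sum()
    return MixtureParameterSet(mus, conc, alpha)


# -- information criteria ----------------------------------------------------

def _pointwise_loglik_draws(fit: FitResult, tracks, max_draws: int = 400):
    """Pointwise (per nonzero bin, depth-weighted) log-likelihood draws."""
    tracks = _as_track_list(tracks)
    draws = fit.draws
    step = max(1, draws.shape[0] // max_draws)
    sub = draws[::step]
    rows = []
    from .distributions import log_pdf as _lp

    for x in sub:
        params = fit.packer.unpack(x)
        point = []
        for s, track in enumerate(tracks):
            obs = track.to_angular()
            mask = obs.weights > 0
            w = obs.weights[mask]
            if isinstance(params, MixtureParameterSet):
                comp = np.stack([
                    _lp(fit.spec, obs.angles[mask], ParameterSet(
                        mu=float(params.mus[m]),
                        concentration=float(params.concentrations[m, s]),
                    ))
                    for m in range(params.M)
                ])
                lp = special.logsumexp(
                    comp + np.log(params.alpha)[:, None], axis=0
                )
            else:
                from .model import _per_sample_params

                lp = _lp(fit.spec, obs.angles[mask], _per_sample_params(params, s))
            point.append(w * lp)
        rows.append(np.concatenate(point))
    return np.asarray(rows)  # (draws, points)


def waic_from_loglik_draws(ll: np.ndarray) -> float:
    """WAIC = -2 * (lppd - p_waic) from a (draws, points) log-likelihood array."""
    lppd = float(np.sum(special.logsumexp(ll, axis=0) - math.log(ll.shape[0])))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic)


def information_criteria(fit: FitResult, tracks, label: str | None = None) -> ICReport:
    """AIC/BIC (both modes) and WAIC (sampling mode) for a fit."""
    tracks = _as_track_list(tracks)
    S = len(tracks)
    M = fit.params.M if fit.is_mixture else 1
    k = k_parameters(fit.spec, S, M)
    n = sum(t.total_T for t in tracks)
    aic = 2.0 * k - 2.0 * fit.loglik
    bic = k * math.log(n) - 2.0 * fit.loglik
    waic = None
    if fit.mode == "sampling" and fit.draws is not None:
        waic = waic_from_loglik_draws(_pointwise_loglik_draws(fit, tracks))
    report = ICReport(
        label=label or f"{fit.spec.family}/{fit.spec.extension}/M={M}",
        k_params=k, loglik=fit.loglik, aic=aic, bic=bic, waic=waic,
    )
    fit.ic.update(aic=aic, bic=bic, **({"waic": waic} if waic is not None else {}))
    return report


def waic(fit: FitResult, tracks) -> float:
    """WAIC of a sampling-mode fit; unavailable for optimizing mode."""
    if fit.mode != "sampling" or fit.draws is None:
        raise ValueError("WAIC requires a sampling-mode fit with stored draws")
    return waic_from_loglik_draws(_pointwise_loglik_draws(fit, tracks))


def likelihood_ratio_test(fit_null: FitResult | float, fit_ext: FitResult | float,
                          df_delta: int) -> float:
    """Wilks chi-squared p-value for a nested model pair (statistic clipped at 0)."""
    ll0 = fit_null.loglik if isinstance(fit_null, FitResult) else float(fit_null)
    ll1 = fit_ext.loglik if isinstance(fit_ext, FitResult) else float(fit_ext)
    stat = 2.0 * (ll1 - ll0)
    if stat < -1e-6:
        warnings.warn(
            f"extended model has lower log-likelihood ({ll1:.4f} < {ll0:.4f}); "
            "the extended fit may not have converged",
            RuntimeWarning,
        )
    return float(stats.chi2.sf(max(stat, 0.0), df_delta))


# -- origin-count selection --------------------------------------------------

@dataclass
class OriginSelection:
    """Per-M information criteria and the chosen number of origins."""

    reports: dict  # M -> ICReport
    fits: dict  # M -> FitResult (MAP)
    best_by_aic: int
    best_by_waic: int
    chosen_M: int


def select_origin_count(tracks, spec: DistributionSpec | None = None,
                        M_range=(1, 2, 3, 4), priors: PriorSpec = PriorSpec(),
                        seed: int = 0, n_seeds: int = 30,
                        mcmc_iterations: int | None = None,
                        mcmc_warmup: int | None = None) -> OriginSelection:
    """Fit M-origin mixtures over ``M_range`` and pick M by AIC and WAIC.

    MAP (multi-seed) supplies the AIC; a sampling run seeded at the MAP
    supplies the WAIC.  Ties break toward smaller M; when AIC and WAIC
    disagree, the smaller of the two winners is chosen (the mixture is a
    singular model, so neither criterion alone is trusted with the larger
    count).
    """
    spec = spec or DistributionSpec("von_mises")
    tracks = _as_track_list(tracks)
    reports, fits = {}, {}
    for M in M_range:
        try:
            fit = fit_map(tracks, spec, priors, n_seeds=n_seeds, seed=seed, M=M)
        except FitFailureError as exc:
            warnings.warn(f"M={M} MAP fit failed: {exc}", RuntimeWarning)
            continue
        try:
            samp = fit_mcmc(
                tracks, spec, priors, seed=seed, M=M, init=fit,
                iterations=mcmc_iterations, warmup=mcmc_warmup,
            )
            w = waic(samp, tracks)
        except Exception as exc:
            warnings.warn(f"M={M} sampling failed: {exc}", RuntimeWarning)
            w = None
        rep = information_criteria(fit, tracks, label=f"M={M}")
        rep.waic = w
        reports[M], fits[M] = rep, fit
    if not reports:
        raise FitFailureError("no mixture size could be fitted")
    best_aic = min(reports, key=lambda M: (reports[M].aic, M))
    with_waic = {M: r for M, r in reports.items() if r.waic is not None}
    best_waic = (
        min(with_waic, key=lambda M: (with_waic[M].waic, M))
        if with_waic else best_aic
    )
    chosen = best_aic if best_aic == best_waic else min(best_aic, best_waic)
    return OriginSelection(reports, fits, best_aic, best_waic, chosen)
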