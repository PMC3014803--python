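"""Species-abundance-distribution (SAD) models: likelihoods and ML fitting.

Four classical models of ranked community abundance are implemented, in
increasing order of the evenness they predict:

* dominance pre-emption (geometric series): each species takes a fixed
  fraction ``k`` of the remaining niche space — 1 free parameter;
* Fisher's log series: ``P(n) = -x**n / (n*log(1-x))`` for counts ``n >= 1``
  — 1 free parameter, with Fisher's alpha derived as ``-S/log(1-x)``;
* Poisson-lognormal: lognormal mean abundances with Poisson sampling,
  zero-truncated — 2 free parameters ``(mu, sigma)``;
* MacArthur's broken stick: simultaneous random partition of a resource —
  0 free parameters.

The log series and Poisson-lognormal are count distributions fitted by
maximum likelihood over species counts.  Pre-emption and broken stick
predict deterministic rank proportions, so their likelihood is the
multinomial of the observed ranked counts against the expected profile
(:func:`multinomial_rank_logL`); that bridge makes all four models
comparable by AIC.  S and N are conditioned on throughout, as is
conventional, so the free-parameter counts for AIC are 1, 1, 2 and 0.

The statsmodels-style entry points are the model classes
(:class:`LogSeries`, :class:`DominancePreemption`, :class:`BrokenStick`,
:class:`PoissonLognormal`): build one from a ranked abundance vector and
call :meth:`~SADModel.fit` (maximum likelihood) or
:meth:`~SADModel.fit_mcmc` (posterior sampling, see
:mod:`commstruct.mcmc`); both return a :class:`SADFitResult`.  The
module-level ``fit_*`` functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special

from .table import AbundanceVector

__all__ = [
    "RankProfile",
    "SADFitResult",
    "SADModel",
    "LogSeries",
    "DominancePreemption",
    "BrokenStick",
    "PoissonLognormal",
    "MODEL_CLASSES",
    "logseries_logpmf",
    "logseries_mean",
    "logseries_x_for_mean",
    "fishers_alpha",
    "preemption_expected_props",
    "brokenstick_expected_props",
    "multinomial_rank_logL",
    "poisson_lognormal_logpmf",
    "aic",
    "fit_logseries",
    "fit_preemption",
    "fit_brokenstick",
    "fit_lognormal",
]

_SIGMA_MIN = 1e-4
_SIGMA_MAX = 50.0


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, AbundanceVector):
        arr = counts.as_array()
    else:
        arr = np.asarray(counts, dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("counts must be a non-empty 1-d sequence")
    if np.any(arr < 1):
        raise ValueError("all counts must be >= 1")
    return arr


# ---------------------------------------------------------------------------
# Log series
# ---------------------------------------------------------------------------

def logseries_logpmf(n, x: float):
    """Log pmf of the Fisher log series, ``P(n) = -x**n/(n*log(1-x))``.

    ``n`` may be a scalar or array of integers >= 1; ``x`` must lie in the
    open interval (0, 1).
    """
    if not 0.0 < x < 1.0:
        raise ValueError(f"x must be in (0, 1), got {x}")
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1")
    out = n_arr * np.log(x) - np.log(n_arr) - np.log(-np.log1p(-x))
    return out if out.ndim else float(out)


def logseries_mean(x: float) -> float:
    """Mean count of the log series, ``-x / ((1-x)*log(1-x))``."""
    if not 0.0 < x < 1.0:
        raise ValueError(f"x must be in (0, 1), got {x}")
    return -x / ((1.0 - x) * np.log1p(-x))


def logseries_x_for_mean(mean: float) -> float:
    """Invert :func:`logseries_mean`: the ``x`` whose mean count is ``mean``.

    The log-series mean tends to 1 as ``x -> 0`` and diverges as ``x -> 1``,
    so any ``mean > 1`` has a unique solution.
    """
    if mean <= 1.0:
        raise ValueError("log-series mean is > 1 for any x in (0,1)")
    return optimize.brentq(
        lambda x: logseries_mean(x) - mean, 1e-12, 1.0 - 1e-14, xtol=1e-14
    )


def fishers_alpha(S: int, x: float) -> float:
    """Fisher's alpha diversity parameter, ``-S / log(1-x)``."""
    return -S / np.log1p(-x)


# ---------------------------------------------------------------------------
# Deterministic rank profiles and the multinomial bridge
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankProfile:
    """Expected rank-abundance proportions for ranks 1..S (sum to 1)."""

    S: int
    expected_props: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.expected_props, dtype=float)
        if p.size != self.S:
            raise ValueError("profile length must equal S")
        if np.any(p <= 0):
            raise ValueError("expected proportions must be positive")
        if np.any(np.diff(p) > 1e-15):
            raise ValueError("expected proportions must be non-increasing")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("expected proportions must sum to 1")
        object.__setattr__(self, "expected_props", p)


def preemption_expected_props(S: int, k: float) -> RankProfile:
    """Geometric-series rank proportions ``k*(1-k)**(i-1) / (1-(1-k)**S)``."""
    if S < 1:
        raise ValueError(f"S must be >= 1, got {S}")
    if not 0.0 < k < 1.0:
        raise ValueError(f"k must be in (0, 1), got {k}")
    i = np.arange(S)
    logp = np.log(k) + i * np.log1p(-k) - np.log(-np.expm1(S * np.log1p(-k)))
    # floor deep-tail ranks at the smallest positive double so log stays finite
    p = np.exp(np.maximum(logp, -743.0))
    return RankProfile(S=S, expected_props=p / p.sum())


def brokenstick_expected_props(S: int) -> RankProfile:
    """Broken-stick rank proportions ``p_i = (1/S) * sum_{j=i..S} 1/j``."""
    if S < 1:
        raise ValueError(f"S must be >= 1, got {S}")
    inv = 1.0 / np.arange(1, S + 1)
    p = np.cumsum(inv[::-1])[::-1] / S
    return RankProfile(S=S, expected_props=p / p.sum())


def multinomial_rank_logL(counts, profile: RankProfile) -> float:
    """Multinomial log-likelihood of ranked counts under a rank profile.

    Includes the multinomial coefficient, so values are comparable across
    profiles on the same data.
    """
    n = _as_counts(counts)
    if n.size != profile.S:
        raise ValueError(
            f"counts length {n.size} does not match profile S={profile.S}"
        )
    N = n.sum()
    p = profile.expected_props
    return float(
        special.gammaln(N + 1)
        - special.gammaln(n + 1).sum()
        + (n * np.log(p)).sum()
    )


# ---------------------------------------------------------------------------
# Poisson-lognormal
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)
_LOG_GH_WEIGHTS = np.log(_GH_WEIGHTS)


def _pln_log_integral(n: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """log of the untruncated Poisson-lognormal mass for counts n >= 0.

    The integral over the latent log-intensity z is evaluated with 64-node
    Gauss-Hermite quadrature centred at the mode of the integrand (found by
    Newton iteration) and scaled by its curvature, which keeps the rule
    accurate for counts far from exp(mu).  Accumulation is in log space.
    """
    n = np.asarray(n, dtype=float)
    s2 = sigma * sigma

    # mode of f(z) = n*z - e^z - (z-mu)^2/(2 s2): solve n - e^z - (z-mu)/s2 = 0
    z = np.where(n > 0, np.log(np.maximum(n, 1.0)), mu - 1.0)
    for _ in range(60):
        ez = np.exp(z)
        g = n - ez - (z - mu) / s2
        gp = -ez - 1.0 / s2
        step = g / gp
        step = np.clip(step, -2.0, 2.0)
        z = z - step
        if np.max(np.abs(step)) < 1e-13:
            break
    h = np.exp(z) + 1.0 / s2  # -f''(z_mode) > 0
    scale = np.sqrt(2.0 / h)

    # z_ij = mode_i + scale_i * t_j ; logI = logsumexp_j(log w_j + f + t^2) + log(scale)
    zz = z[:, None] + scale[:, None] * _GH_NODES[None, :]
    with np.errstate(over="ignore"):  # exp overflow at far nodes -> -inf in f
        f = (
            n[:, None] * zz
            - np.exp(zz)
            - special.gammaln(n + 1.0)[:, None]
            - (zz - mu) ** 2 / (2.0 * s2)
            - 0.5 * np.log(2.0 * np.pi * s2)
        )
    return special.logsumexp(
        f + _GH_NODES[None, :] ** 2 + _LOG_GH_WEIGHTS[None, :], axis=1
    ) + np.log(scale)


def poisson_lognormal_logpmf(n, mu: float, sigma: float):
    """Log pmf of the zero-truncated Poisson-lognormal distribution.

    ``P(n) = I(n) / (1 - I(0))`` where ``I(n)`` is the Poisson mass with
    lognormal-distributed intensity ``exp(z)``, ``z ~ Normal(mu, sigma**2)``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    n_arr = np.atleast_1d(np.asarray(n))
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1 (zero-truncated)")
    log_i = _pln_log_integral(n_arr.astype(float), mu, sigma)
    log_p0 = min(_pln_log_integral(np.array([0.0]), mu, sigma)[0], -1e-15)
    # log(1 - exp(log_p0)), stable for log_p0 near 0 and very negative
    if log_p0 > -0.693:
        log_trunc = np.log(-np.expm1(log_p0))
    else:
        log_trunc = np.log1p(-np.exp(log_p0))
    out = log_i - log_trunc
    return out if np.ndim(n) else float(out[0])


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class SADFitResult:
    """Fit of one SAD model to one ranked abundance vector.

    Attributes
    ----------
    name : model identifier ("preemption", "logseries", "lognormal",
        "brokenstick").
    params : dict of estimated free parameters (empty for broken stick).
    llf : maximised log-likelihood in nats.
    aic : ``2*k - 2*llf`` with ``k = len(params)``.
    converged : whether the optimiser (or chain diagnostic) succeeded.
    derived : derived quantities (e.g. Fisher's alpha for the log series).
    posterior : for MCMC fits, dict with "samples" (draws x k array),
        "log_like" per draw, and "diagnostics" (r_hat, acceptance).
    """

    name: str
    params: dict
    llf: float
    aic: float
    nobs: int
    ntotal: int
    converged: bool = True
    method: str = "mle"
    derived: dict = field(default_factory=dict)
    bse: dict = field(default_factory=dict)
    posterior: Optional[dict] = None
    message: str = ""

    @property
    def k_params(self) -> int:
        return len(self.params)

    def to_dict(self) -> dict:
        d = {
            "model": self.name,
            "params": {k: float(v) for k, v in self.params.items()},
            "logL_max": float(self.llf),
            "aic": float(self.aic),
            "n_free_params": self.k_params,
            "S": self.nobs,
            "N": self.ntotal,
            "converged": bool(self.converged),
            "method": self.method,
        }
        if self.derived:
            d["derived"] = {k: float(v) for k, v in self.derived.items()}
        if self.posterior is not None:
            d["mcmc"] = {
                "n_draws": int(self.posterior["samples"].shape[0]),
                "diagnostics": {
                    k: float(v) for k, v in self.posterior["diagnostics"].items()
                },
                "seed": self.posterior.get("seed"),
            }
        if self.message:
            d["message"] = self.message
        return d

    def summary(self) -> str:
        lines = [
            f"SAD model: {self.name} ({self.method})",
            f"  S = {self.nobs}, N = {self.ntotal}",
            f"  logL = {self.llf:.4f}   AIC = {self.aic:.4f}   "
            f"free params = {self.k_params}",
        ]
        for pname, val in self.params.items():
            se = self.bse.get(pname)
            post = ""
            if self.posterior is not None:
                idx = list(self.params).index(pname)
                draws = self.posterior["samples"][:, idx]
                post = f"   posterior mean {draws.mean():.5g} sd {draws.std():.3g}"
            se_txt = f" (se {se:.3g})" if se is not None else ""
            lines.append(f"  {pname} = {val:.6g}{se_txt}{post}")
        for dname, val in self.derived.items():
            lines.append(f"  {dname} = {val:.6g} (derived)")
        if not self.converged:
            lines.append(f"  WARNING: not converged: {self.message}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------

class SADModel:
    """Base class: a SAD model bound to one ranked abundance vector."""

    name: str = ""
    param_names: Sequence[str] = ()

    def __init__(self, counts):
        self.counts = _as_counts(counts)
        self.nobs = int(self.counts.size)  # S
        self.ntotal = int(self.counts.sum())  # N

    @property
    def k_params(self) -> int:
        return len(self.param_names)

    # -- subclass API ------------------------------------------------------
    def loglike(self, params: np.ndarray) -> float:
        raise NotImplementedError

    def log_prior(self, params: np.ndarray) -> float:
        raise NotImplementedError

    def _start_points(self) -> np.ndarray:
        """Deterministic optimisation start(s), shape (n_starts, k)."""
        raise NotImplementedError

    def fit(self) -> SADFitResult:
        raise NotImplementedError

    # -- shared ------------------------------------------------------------
    def refine(self, params0: np.ndarray) -> tuple[np.ndarray, float, bool]:
        """Local likelihood maximisation from params0 (used by MCMC too)."""
        raise NotImplementedError

    def fit_mcmc(self, seed: int, chain=None) -> SADFitResult:
        from . import mcmc

        if self.k_params == 0:
            raise ValueError(f"{self.name} has no free parameters to sample")
        return mcmc.mcmc_fit(self, seed=seed, chain=chain)

    def _result(self, params, llf, converged=True, message="", **kw) -> SADFitResult:
        pdict = dict(zip(self.param_names, np.atleast_1d(params))) if self.k_params else {}
        return SADFitResult(
            name=self.name,
            params=pdict,
            llf=float(llf),
            aic=aic(llf, self.k_params),
            nobs=self.nobs,
            ntotal=self.ntotal,
            converged=converged,
            message=message,
            **kw,
        )


class LogSeries(SADModel):
    """Fisher log series fitted to species counts by maximum likelihood.

    The ML estimate of ``x`` solves ``sample mean = -x/((1-x)*log(1-x))``
    (the score equation), found by bracketed root-finding; Fisher's alpha is
    reported as the derived quantity ``-S/log(1-x)``.
    """

    name = "logseries"
    param_names = ("x",)

    def loglike(self, params) -> float:
        x = float(np.atleast_1d(params)[0])
        if not 0.0 < x < 1.0:
            return -np.inf
        return float(logseries_logpmf(self.counts, x).sum())

    def log_prior(self, params) -> float:
        x = float(np.atleast_1d(params)[0])
        return 0.0 if 0.0 < x < 1.0 else -np.inf

    def _start_points(self) -> np.ndarray:
        mean = self.ntotal / self.nobs
        x0 = logseries_x_for_mean(mean) if mean > 1 else 1e-6
        return np.array([[x0]])

    def refine(self, params0):
        res = optimize.minimize_scalar(
            lambda x: -self.loglike([x]),
            bounds=(1e-12, 1.0 - 1e-12),
            method="bounded",
            options={"xatol": 1e-13},
        )
        x0 = float(np.atleast_1d(params0)[0])
        if -res.fun >= self.loglike([x0]):
            return np.array([res.x]), float(-res.fun), bool(res.success)
        return np.array([x0]), self.loglike([x0]), True

    def fit(self) -> SADFitResult:
        mean = self.ntotal / self.nobs
        if mean <= 1.0:
            warnings.warn(
                "all counts equal 1: log-series x is at its lower boundary",
                stacklevel=2,
            )
            x_hat = 1e-9
            return self._result(
                [x_hat],
                self.loglike([x_hat]),
                converged=True,
                message="x at lower boundary (all singletons)",
                derived={"fishers_alpha": fishers_alpha(self.nobs, x_hat)},
            )
        x_hat = logseries_x_for_mean(mean)
        llf = self.loglike([x_hat])
        return self._result(
            [x_hat],
            llf,
            derived={"fishers_alpha": fishers_alpha(self.nobs, x_hat)},
            bse={"x": self._se(x_hat)},
        )

    def _se(self, x_hat: float) -> float:
        # observed information by central difference of the score
        h = min(1e-6, x_hat / 10, (1 - x_hat) / 10)
        d2 = (
            self.loglike([x_hat + h])
            - 2 * self.loglike([x_hat])
            + self.loglike([x_hat - h])
        ) / h**2
        return float(1.0 / np.sqrt(-d2)) if d2 < 0 else np.nan


class DominancePreemption(SADModel):
    """Dominance pre-emption (geometric series) via the multinomial bridge.

    ``k`` is estimated by bounded scalar maximisation of the multinomial
    log-likelihood of the ranked counts against the geometric rank profile.
    """

    name = "preemption"
    param_names = ("k",)

    def loglike(self, params) -> float:
        k = float(np.atleast_1d(params)[0])
        if not 0.0 < k < 1.0:
            return -np.inf
        return multinomial_rank_logL(self.counts, preemption_expected_props(self.nobs, k))

    def log_prior(self, params) -> float:
        k = float(np.atleast_1d(params)[0])
        return 0.0 if 0.0 < k < 1.0 else -np.inf

    def _start_points(self) -> np.ndarray:
        # slope of log-counts vs rank gives a geometric-decay moment start
        if self.nobs >= 2:
            slope = np.polyfit(
                np.arange(self.nobs), np.log(self.counts.astype(float)), 1
            )[0]
            k0 = float(np.clip(-np.expm1(slope), 1e-4, 1 - 1e-4))
        else:
            k0 = 0.5
        return np.array([[k0]])

    def refine(self, params0):
        res = optimize.minimize_scalar(
            lambda k: -self.loglike([k]),
            bounds=(1e-9, 1.0 - 1e-9),
            method="bounded",
            options={"xatol": 1e-12},
        )
        k0 = float(np.atleast_1d(params0)[0])
        if -res.fun >= self.loglike([k0]):
            return np.array([res.x]), float(-res.fun), bool(res.success)
        return np.array([k0]), self.loglike([k0]), True

    def fit(self) -> SADFitResult:
        if self.nobs < 2:
            raise ValueError("pre-emption fit needs S >= 2")
        params, llf, ok = self.refine(self._start_points()[0])
        return self._result(params, llf, converged=ok,
                            message="" if ok else "scalar optimiser failed")


class BrokenStick(SADModel):
    """MacArthur's broken stick: no free parameters, AIC = -2*logL."""

    name = "brokenstick"
    param_names = ()

    def loglike(self, params=()) -> float:
        return multinomial_rank_logL(
            self.counts, brokenstick_expected_props(self.nobs)
        )

    def fit(self) -> SADFitResult:
        return self._result([], self.loglike())


class PoissonLognormal(SADModel):
    """Zero-truncated Poisson-lognormal fitted by multi-start ML.

    Five deterministic starts (method-of-moments on log counts, plus
    perturbations of mu and sigma) guard against the multimodality the
    likelihood can show at small S; the best local optimum is kept.
    """

    name = "lognormal"
    param_names = ("mu", "sigma")

    def loglike(self, params) -> float:
        mu, sigma = np.atleast_1d(params)
        if not _SIGMA_MIN <= sigma <= _SIGMA_MAX:
            return -np.inf
        return float(poisson_lognormal_logpmf(self.counts, float(mu), float(sigma)).sum())

    def log_prior(self, params) -> float:
        mu, sigma = np.atleast_1d(params)
        if sigma <= 0:
            return -np.inf
        # mu ~ Normal(0, sd 10); sigma ~ Half-Normal(sd 5)
        return float(-0.5 * (mu / 10.0) ** 2 - 0.5 * (sigma / 5.0) ** 2)

    def _start_points(self) -> np.ndarray:
        logn = np.log(self.counts.astype(float))
        mu0 = float(logn.mean())
        s0 = float(max(logn.std(), 0.1))
        return np.array(
            [
                [mu0, s0],
                [mu0 + 0.5, s0],
                [mu0 - 0.5, s0],
                [mu0, 1.5 * s0],
                [mu0, max(0.5 * s0, 2 * _SIGMA_MIN)],
            ]
        )

    def refine(self, params0):
        p0 = np.atleast_1d(np.asarray(params0, dtype=float))

        def nll(theta):
            mu, logsig = theta
            return -self.loglike([mu, np.exp(logsig)])

        res = optimize.minimize(
            nll,
            [p0[0], np.log(np.clip(p0[1], _SIGMA_MIN, _SIGMA_MAX))],
            method="L-BFGS-B",
            bounds=[(-50, 50), (np.log(_SIGMA_MIN), np.log(_SIGMA_MAX))],
        )
        params = np.array([res.x[0], np.exp(res.x[1])])
        llf = -float(res.fun)
        llf0 = self.loglike(p0)
        if llf >= llf0:
            return params, llf, bool(res.success)
        return p0, llf0, True

    def fit(self) -> SADFitResult:
        if self.nobs < 3:
            raise ValueError("Poisson-lognormal fit needs S >= 3 (2 parameters)")
        best = None
        any_ok = False
        for start in self._start_points():
            params, llf, ok = self.refine(start)
            any_ok = any_ok or ok
            if best is None or llf > best[1]:
                best = (params, llf, ok)
        params, llf, ok = best
        msg = ""
        if params[1] <= _SIGMA_MIN * (1 + 1e-6):
            msg = "sigma at lower bound (counts carry no overdispersion)"
            warnings.warn(msg, stacklevel=2)
        return self._result(
            params, llf, converged=any_ok, message=msg or ("" if any_ok else "no start converged")
        )


MODEL_CLASSES = {
    cls.name: cls
    for cls in (DominancePreemption, LogSeries, PoissonLognormal, BrokenStick)
}


# ---------------------------------------------------------------------------
# Functional wrappers and AIC
# ---------------------------------------------------------------------------

def aic(logL_max: float, n_free_params: int) -> float:
    """Akaike Information Criterion, ``2k - 2*logL_max`` (lower is better)."""
    if n_free_params < 0:
        raise ValueError("n_free_params must be >= 0")
    return 2.0 * n_free_params - 2.0 * float(logL_max)


def fit_logseries(counts) -> SADFitResult:
    return LogSeries(counts).fit()


def fit_preemption(counts) -> SADFitResult:
    return DominancePreemption(counts).fit()


def fit_brokenstick(counts) -> SADFitResult:
    return BrokenStick(counts).fit()


def fit_lognormal(counts) -> SADFitResult:
    return PoissonLognormal(counts).fit()
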