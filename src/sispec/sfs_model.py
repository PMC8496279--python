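"""Poisson random-field models for class-specific unfolded SFSs.

The statistical core of the package: the expected unfolded site frequency
spectrum for a semidominant directional force of scaled strength
``gamma = 4*Ne*s``, and a family of nested Poisson likelihood models used to
estimate ``gamma`` and the mutational bias ``kappa = u/v`` from the three
class SFSs (S>W, W>S, neutral), in the presence of demographic SFS distortion
and possible ancestral-state misorientation.

Expected SFS
------------
For a mutation favored with coefficient ``gamma``, the expected number of
sites at derived count ``j`` in a sample of ``n`` haploids is

    E[xi_j] = theta * C(n, j) * Int_0^1 u(gamma, x) x^j (1-x)^(n-j) dx

with the scaled sojourn density

    u(gamma, x) = (1 - exp(-gamma (1-x))) / ((1 - exp(-gamma)) x (1-x)),

which reduces to ``theta / j`` in the neutral limit.  The W>S class uses
``+gamma``, S>W uses ``-gamma`` and the GC-conservative class is neutral.

Models
------
M0   : gamma = 0, free class thetas and distortion.
M1   : gamma free.
M0*/M1*: as above plus a misorientation probability ``epsilon`` mixing each
class with the frequency-reflected spectrum of the opposite class.

All models share one distortion vector ``r_j`` (j = 2..n-1, ``r_1 = 1`` for
identifiability) across the three classes, following the rationale that
demography distorts every class equally while the directional force does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2

from .sfs import CLASSES, OPPOSITE, ClassSFS

__all__ = [
    "GbgcFit",
    "expected_sfs",
    "sfs_cell_means",
    "model_loglik",
    "fit_model",
    "likelihood_ratio_test",
    "MODELS",
]

MODELS = ("M0", "M0*", "M1", "M1*")

#: Directly nested model pairs (null, alternative) -> df of the LRT.
NESTED_PAIRS = {
    ("M0", "M1"): 1,
    ("M0*", "M1*"): 1,
    ("M0", "M0*"): 1,
    ("M1", "M1*"): 1,
    ("M0", "M1*"): 2,
}

GAMMA_MAX = 50.0
_SMALL_GAMMA = 1e-6

# Fixed-order Gauss-Legendre rule on (0, 1); the integrand is smooth once the
# x(1-x) singularities are cancelled against the binomial kernel, so order 64
# integrates it essentially to machine precision for the sample sizes used.
_GL_ORDER = 64
_nodes, _weights = leggauss(_GL_ORDER)
_GL_X = 0.5 * (_nodes + 1.0)
_GL_W = 0.5 * _weights

# Per-sample-size cache of the weighted binomial kernel
# A[k, j-1] = w_k * C(n, j) * x_k^(j-1) * (1-x_k)^(n-j-1).
_KERNEL_CACHE: dict[int, np.ndarray] = {}


def _binomial_kernel(n: int) -> np.ndarray:
    A = _KERNEL_CACHE.get(n)
    if A is None:
        j = np.arange(1, n)
        logc = gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
        logx = np.log(_GL_X)[:, None]
        log1mx = np.log1p(-_GL_X)[:, None]
        A = np.exp(logc[None, :] + (j - 1) * logx + (n - j - 1) * log1mx)
        A *= _GL_W[:, None]
        _KERNEL_CACHE[n] = A
    return A


def _sojourn_factor(gamma: float, x: np.ndarray) -> np.ndarray:
    """(1 - e^{-gamma(1-x)}) / (1 - e^{-gamma}), with its gamma -> 0 limit."""
    if abs(gamma) < _SMALL_GAMMA:
        # second-order expansion around gamma = 0
        return (1.0 - x) * (1.0 + 0.5 * gamma * x)
    return np.expm1(-gamma * (1.0 - x)) / np.expm1(-gamma)


def expected_sfs(gamma: float, theta: float, n: int) -> np.ndarray:
    """Expected unfolded SFS counts at derived counts j = 1..n-1.

    Parameters
    ----------
    gamma:
        Scaled coefficient of the directional force favoring the derived
        allele (``4*Ne*s``, semidominant).
    theta:
        Scaled mutational input of the class; the neutral spectrum is
        ``theta / j``.
    n:
        Haploid sample size.
    """
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if abs(gamma) > GAMMA_MAX:
        raise ValueError(f"|gamma| > {GAMMA_MAX} exceeds the supported numeric range")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    if abs(gamma) < _SMALL_GAMMA and gamma == 0.0:
        return theta / np.arange(1, n)
    g = _sojourn_factor(gamma, _GL_X)
    return theta * (g @ _binomial_kernel(n))


@dataclass
class GbgcFit:
    """A fitted SFS model.

    ``kappa`` is a derived quantity, ``(theta_sw / L_S) / (theta_ws / L_W)``:
    the per-site strong-to-weak mutational input over the weak-to-strong one.
    """

    model: str
    n: int
    gamma: float
    theta_ws: float
    theta_sw: float
    theta_neu: float
    distortion: np.ndarray  # length n-1, distortion[0] == 1
    epsilon: float
    loglik: float
    kappa: float = np.nan
    converged: bool = True
    n_restarts: int = 1
    message: str = ""

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        self.distortion = np.asarray(self.distortion, dtype=float)
        if self.distortion.shape != (self.n - 1,):
            raise ValueError("distortion must have length n - 1")
        if not np.isclose(self.distortion[0], 1.0):
            raise ValueError("r_1 must equal 1 (identifiability constraint)")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")

    @property
    def thetas(self) -> dict[str, float]:
        return {"S>W": self.theta_sw, "W>S": self.theta_ws, "neutral": self.theta_neu}

    @property
    def n_parameters(self) -> int:
        k = 3 + (self.n - 2)  # thetas + r_2..r_{n-1}
        if self.model in ("M1", "M1*"):
            k += 1
        if self.model in ("M0*", "M1*"):
            k += 1
        return k


def sfs_cell_means(
    gamma: float,
    theta_ws: float,
    theta_sw: float,
    theta_neu: float,
    n: int,
    distortion: np.ndarray | None = None,
    epsilon: float = 0.0,
) -> dict[str, np.ndarray]:
    """Expected counts per class and frequency cell under the full model.

    The demographic distortion multiplies the true spectrum of every class at
    its true frequency; misorientation then swaps a fraction ``epsilon`` of
    each class with the frequency-reflected opposite class (neutral reflects
    onto itself).
    """
    base = {
        "S>W": expected_sfs(-gamma, theta_sw, n),
        "W>S": expected_sfs(gamma, theta_ws, n),
        "neutral": theta_neu / np.arange(1, n),
    }
    if distortion is not None:
        r = np.asarray(distortion, dtype=float)
        base = {c: r * v for c, v in base.items()}
    if epsilon == 0.0:
        return base
    return {
        c: (1.0 - epsilon) * base[c] + epsilon * base[OPPOSITE[c]][::-1]
        for c in CLASSES
    }


def _poisson_loglik(observed: np.ndarray, mean: np.ndarray) -> float:
    o = observed.ravel()
    m = mean.ravel()
    bad = (m <= 0) & (o > 0)
    if np.any(bad):
        return -np.inf
    ok = m > 0
    return float(np.sum(o[ok] * np.log(m[ok]) - m[ok] - gammaln(o[ok] + 1.0)) - m[~ok].sum())


def model_loglik(sfs: ClassSFS, fit: GbgcFit) -> float:
    """Independent-Poisson log likelihood of ``sfs`` under a fitted model."""
    if fit.n != sfs.n:
        raise ValueError("fit and SFS sample sizes differ")
    means = sfs_cell_means(
        fit.gamma,
        fit.theta_ws,
        fit.theta_sw,
        fit.theta_neu,
        fit.n,
        distortion=fit.distortion,
        epsilon=fit.epsilon,
    )
    obs = np.stack([sfs.xi[c] for c in CLASSES])
    mean = np.stack([means[c] for c in CLASSES])
    return _poisson_loglik(obs, mean)


def _unpack(x: np.ndarray, n: int, model: str):
    theta_ws, theta_sw, theta_neu = np.exp(x[:3])
    r = np.ones(n - 1)
    r[1:] = np.exp(x[3 : 3 + n - 2])
    k = 3 + n - 2
    gamma = 0.0
    if model in ("M1", "M1*"):
        gamma = x[k]
        k += 1
    eps = 0.0
    if model in ("M0*", "M1*"):
        eps = x[k]
    return gamma, theta_ws, theta_sw, theta_neu, r, eps


def fit_model(
    sfs: ClassSFS,
    model: str = "M1",
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = None,
) -> GbgcFit:
    """Maximum-likelihood fit of one of the nested SFS models.

    Uses bounded quasi-Newton (L-BFGS-B) on log-transformed positive
    parameters with seed-controlled jittered multi-starts; returns the best
    converged fit.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    for c in CLASSES:
        if sfs.xi[c].sum() <= 0:
            raise ValueError(f"degenerate SFS: class {c!r} has no segregating sites")
    n = sfs.n
    rng = np.random.default_rng(seed)
    j = np.arange(1, n)
    a_n = np.sum(1.0 / j)
    obs = np.stack([sfs.xi[c] for c in CLASSES])

    def negloglik(x: np.ndarray) -> float:
        gamma, tw, ts, tn, r, eps = _unpack(x, n, model)
        means = sfs_cell_means(gamma, tw, ts, tn, n, distortion=r, epsilon=eps)
        ll = _poisson_loglik(obs, np.stack([means[c] for c in CLASSES]))
        return -ll if np.isfinite(ll) else 1e300

    # method-of-moments starting thetas: total counts over the neutral a_n sum
    theta0 = np.array(
        [
            max(sfs.xi["W>S"].sum() / a_n, 1e-6),
            max(sfs.xi["S>W"].sum() / a_n, 1e-6),
            max(sfs.xi["neutral"].sum() / a_n, 1e-6),
        ]
    )
    ndim = 3 + (n - 2) + (model in ("M1", "M1*")) + (model in ("M0*", "M1*"))
    bounds = [(-20.0, 30.0)] * 3 + [(-10.0, 10.0)] * (n - 2)
    if model in ("M1", "M1*"):
        bounds.append((-25.0, 25.0))
    if model in ("M0*", "M1*"):
        bounds.append((0.0, 0.499))

    best = None
    for i in range(max(1, n_restarts)):
        x0 = np.zeros(ndim)
        x0[:3] = np.log(theta0)
        if i > 0:
            x0[:3] += rng.normal(0.0, 0.3, size=3)
            x0[3 : 3 + n - 2] = rng.normal(0.0, 0.1, size=n - 2)
        k = 3 + n - 2
        if model in ("M1", "M1*"):
            x0[k] = 0.0 if i == 0 else rng.normal(0.0, 1.0)
            k += 1
        if model in ("M0*", "M1*"):
            x0[k] = 0.02 if i == 0 else rng.uniform(0.0, 0.2)
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 2000, "maxfun": 200000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")

    gamma, tw, ts, tn, r, eps = _unpack(best.x, n, model)
    kappa = np.nan
    if sfs.L_S > 0 and sfs.L_W > 0 and tw > 0:
        kappa = (ts / sfs.L_S) / (tw / sfs.L_W)
    return GbgcFit(
        model=model,
        n=n,
        gamma=float(gamma),
        theta_ws=float(tw),
        theta_sw=float(ts),
        theta_neu=float(tn),
        distortion=r,
        epsilon=float(eps),
        loglik=float(-best.fun),
        kappa=float(kappa),
        converged=bool(best.success),
        n_restarts=max(1, n_restarts),
        message=str(best.message),
    )


def likelihood_ratio_test(fit_null: GbgcFit, fit_alt: GbgcFit):
    """LRT between two nested fits: returns (statistic, df, p)."""
    key = (fit_null.model, fit_alt.model)
    if key not in NESTED_PAIRS:
        raise ValueError(f"models {key} are not a nested (null, alternative) pair")
    if fit_null.n != fit_alt.n:
        raise ValueError("fits were made at different sample sizes")
    df = NESTED_PAIRS[key]
    stat = max(2.0 * (fit_alt.loglik - fit_null.loglik), 0.0)
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p
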