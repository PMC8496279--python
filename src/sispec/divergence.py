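"""Lineage-specific W/S substitution counting and equilibrium algebra.

Divergence between the two ingroup species is analyzed on the rooted
three-taxon tree ((ingroup1, ingroup2), outgroup).  A nonstationary
GTR-style model — shared exchangeabilities, free root composition and free
branch-specific target compositions — is fitted to the 64 site-pattern
counts by maximum likelihood, and the expected numbers of labelled
substitutions (S>W, W>S, GC-conservative) on each branch are computed by
expected Markov counting: the closed-form expected number of labelled state
changes of the continuous-time chain conditional on the branch endpoints,
averaged over the posterior distribution of ancestral states.  Ancestral
GC/AT site totals are posterior expectations as well, so no single "best"
ancestral sequence is ever committed to.

The module also carries the closed-form equilibrium relations between the
mutational bias kappa, the fixation bias gamma, the equilibrium GC content
GC* = 1 / (1 + kappa e^(-gamma)) and the substitution-rate ratio
R = r_S>W / r_W>S = kappa e^(-gamma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "NonstationaryModel",
    "SubstitutionCounts",
    "pattern_counts",
    "fit_nonstationary",
    "nonstationarity_test",
    "expected_substitution_counts",
    "expected_labelled_counts",
    "equilibrium_chi2",
    "gc_equilibrium",
    "solve_gamma_for_gc",
    "substitution_ratio_R",
    "required_kappa",
]

log = logging.getLogger(__name__)

BASES = "ACGT"
_STRONG = np.array([False, True, True, False])  # C, G
BRANCHES = ("anc", "out", "in1", "in2")  # root->anc, root->out, anc->in1, anc->in2

# label masks over ordered state pairs (i -> j), diagonal always False
_OFF = ~np.eye(4, dtype=bool)
MASK_SW = np.outer(_STRONG, ~_STRONG) & _OFF
MASK_WS = np.outer(~_STRONG, _STRONG) & _OFF
MASK_NEU = (np.outer(_STRONG, _STRONG) | np.outer(~_STRONG, ~_STRONG)) & _OFF
LABELS = {"S>W": MASK_SW, "W>S": MASK_WS, "neutral": MASK_NEU}


# ---------------------------------------------------------------------------
# closed-form equilibrium algebra


def gc_equilibrium(kappa: float, gamma: float) -> float:
    """Equilibrium GC content 1 / (1 + kappa e^(-gamma))."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return 1.0 / (1.0 + kappa * np.exp(-gamma))


def solve_gamma_for_gc(gc: float, kappa: float) -> float:
    """The gamma at which the equilibrium GC content equals ``gc``."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return float(-np.log((1.0 - gc) / (gc * kappa)))


def substitution_ratio_R(kappa: float, gamma: float) -> float:
    """R = kappa e^(-gamma): the S>W over W>S substitution-rate ratio for a
    semidominant fixation bias gamma; equals kappa under strict neutrality."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return float(kappa * np.exp(-gamma))


def required_kappa(gc: float) -> float:
    """Mutational bias required for neutral equilibrium at GC content ``gc``."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    return (1.0 - gc) / gc


def equilibrium_chi2(n_ws: float, n_sw: float) -> tuple[float, float]:
    """Pearson goodness-of-fit test of W>S vs S>W counts against 1:1.

    No continuity correction; df = 1.  Returns (statistic, p).
    """
    if n_ws < 0 or n_sw < 0:
        raise ValueError("counts must be non-negative")
    total = n_ws + n_sw
    if total == 0:
        raise ValueError("chi-square undefined for zero total count")
    expected = total / 2.0
    stat = (n_ws - expected) ** 2 / expected + (n_sw - expected) ** 2 / expected
    return float(stat), float(chi2_dist.sf(stat, 1))


# ---------------------------------------------------------------------------
# nonstationary three-taxon model


@dataclass
class NonstationaryModel:
    exchangeabilities: np.ndarray  # (AC, AG, AT, CG, CT, GT), GT = 1
    root_pi: np.ndarray
    branch_pi: dict[str, np.ndarray]
    branch_lengths: dict[str, float]
    loglik: float
    loglik_stationary: float
    n_runs: int
    converged: bool = True
    stationary: bool = False

    def rate_matrix(self, branch: str) -> np.ndarray:
        return _gtr_q(self.exchangeabilities, self.branch_pi[branch])

    def transition_matrix(self, branch: str) -> np.ndarray:
        return expm(self.rate_matrix(branch) * self.branch_lengths[branch])


def _gtr_q(exch: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """GTR rate matrix with target composition ``pi``, normalized to one
    expected substitution per site at the target composition."""
    S = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    S[iu] = exch
    S += S.T
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(pi * np.diag(Q))
    return Q / mu


def pattern_counts(in1, in2, out) -> np.ndarray:
    """Site-pattern counts over (in1, in2, out) as a length-64 vector."""
    a = _as_states(in1)
    b = _as_states(in2)
    c = _as_states(out)
    idx = a * 16 + b * 4 + c
    return np.bincount(idx, minlength=64).astype(float)


def _as_states(x) -> np.ndarray:
    if isinstance(x, str):
        lut = {b: i for i, b in enumerate(BASES)}
        return np.array([lut[ch] for ch in x.upper()])
    return np.asarray(x).ravel()


def _softmax(z3: np.ndarray) -> np.ndarray:
    z = np.concatenate([z3, [0.0]])
    e = np.exp(z - z.max())
    return e / e.sum()


def _pattern_loglik(counts64, exch, root_pi, pis, ts):
    P = {b: expm(_gtr_q(exch, pis[b]) * ts[b]) for b in BRANCHES}
    # W[x, c] = sum_r root[r] P_anc[r, x] P_out[r, c]
    W = np.einsum("r,rx,rc->xc", root_pi, P["anc"], P["out"])
    L = np.einsum("xc,xa,xb->abc", W, P["in1"], P["in2"]).ravel()
    if np.any((L <= 0) & (counts64 > 0)):
        return -np.inf
    ok = L > 0
    return float(np.sum(counts64[ok] * np.log(L[ok])))


def _unpack_params(x, stationary: bool):
    exch = np.ones(6)
    exch[:5] = np.exp(x[:5])
    k = 5
    root_pi = _softmax(x[k : k + 3])
    k += 3
    if stationary:
        pis = {b: root_pi for b in BRANCHES}
    else:
        pis = {}
        for b in BRANCHES:
            pis[b] = _softmax(x[k : k + 3])
            k += 3
    ts = {}
    for b in BRANCHES:
        ts[b] = np.exp(x[k])
        k += 1
    return exch, root_pi, pis, ts


def _fit(counts64, stationary, n_runs, rng):
    ndim = 5 + 3 + (0 if stationary else 12) + 4
    # moment-based starting composition from the observed leaf frequencies
    leaf_freq = np.zeros(4)
    c3 = counts64.reshape(4, 4, 4)
    leaf_freq += c3.sum(axis=(1, 2)) + c3.sum(axis=(0, 2)) + c3.sum(axis=(0, 1))
    leaf_freq /= leaf_freq.sum()
    pi_logit = np.log(np.maximum(leaf_freq, 1e-6))
    pi_logit = (pi_logit - pi_logit[3])[:3]

    def neg(x):
        ll = _pattern_loglik(counts64, *_unpack_params(x, stationary))
        return -ll if np.isfinite(ll) else 1e300

    best = None
    for run in range(max(1, n_runs)):
        x0 = np.zeros(ndim)
        x0[:5] = np.log(1.0 + rng.uniform(-0.2, 0.2, 5)) if run else 0.0
        x0[5:8] = pi_logit
        k = 8
        if not stationary:
            for _ in BRANCHES:
                x0[k : k + 3] = pi_logit + (rng.normal(0, 0.2, 3) if run else 0.0)
                k += 3
        x0[k:] = np.log(0.08) + (rng.normal(0, 0.5, 4) if run else 0.0)
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(-8, 8)] * (ndim - 4) + [(-9.0, 2.0)] * 4,
                       options={"maxiter": 1500, "maxfun": 100000})
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_nonstationary(
    alignments, n_runs: int = 10, seed: int | np.random.Generator | None = None
) -> NonstationaryModel:
    """ML fit of the nonstationary model and of the stationary GTR.

    ``alignments`` is either a length-64 pattern-count vector or a tuple
    ``(in1, in2, out)`` of equal-length sequences / state arrays.
    """
    counts64 = (
        np.asarray(alignments, dtype=float)
        if np.ndim(alignments) == 1 and np.size(alignments) == 64
        else pattern_counts(*alignments)
    )
    rng = np.random.default_rng(seed)
    best_nh = _fit(counts64, False, n_runs, rng)
    best_st = _fit(counts64, True, max(1, n_runs // 2), rng)
    if best_nh is None or not np.isfinite(best_nh.fun):
        raise RuntimeError("nonstationary fit failed in every run")
    exch, root_pi, pis, ts = _unpack_params(best_nh.x, False)
    return NonstationaryModel(
        exchangeabilities=exch,
        root_pi=root_pi,
        branch_pi=pis,
        branch_lengths=ts,
        loglik=-best_nh.fun,
        loglik_stationary=-best_st.fun,
        n_runs=max(1, n_runs),
        converged=bool(best_nh.success),
    )


def nonstationarity_test(model: NonstationaryModel) -> tuple[float, int, float]:
    """LRT of the nonstationary model against the stationary GTR.

    df = 12: four branch compositions (3 free parameters each) replace the
    shared stationary composition, and the root composition decouples.
    """
    stat = max(2.0 * (model.loglik - model.loglik_stationary), 0.0)
    df = 12
    return stat, df, float(chi2_dist.sf(stat, df))


# ---------------------------------------------------------------------------
# expected Markov counting


def expected_labelled_counts(
    Q: np.ndarray, t: float, mask: np.ndarray, method: str = "eig"
) -> np.ndarray:
    """J[a, b] = E[# labelled i->j events on (0, t); X_t = b | X_0 = a] * P_ab
    for the CTMC with generator ``Q`` — i.e. the joint quantity; divide by
    the transition matrix for the endpoint-conditional expectation.

    ``method='eig'`` uses the eigendecomposition closed form; ``'uniform'``
    uses uniformization (series truncated at Poisson tail < 1e-12), the
    fallback when the eigenvector matrix is ill-conditioned.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    E = np.where(mask, Q, 0.0)
    if t == 0:
        return np.zeros_like(Q)
    if method == "eig":
        lam, U = np.linalg.eig(Q)
        cond = np.linalg.cond(U)
        if not np.isfinite(cond) or cond > 1e8:
            return expected_labelled_counts(Q, t, mask, method="uniform")
        Uinv = np.linalg.inv(U)
        G = Uinv @ E @ U
        lt = lam * t
        el = np.exp(lt)
        # Phi_kl = (e^{lam_k t} - e^{lam_l t}) / (lam_k - lam_l), t e^{lam t} on ties
        dl = lam[:, None] - lam[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            Phi = (el[:, None] - el[None, :]) / dl
        tie = np.abs(dl) < 1e-12
        Phi[tie] = (t * el[:, None] * np.ones_like(Phi))[tie]
        J = U @ (G * Phi) @ Uinv  # integral over s in (0, t)
        return np.real(J)
    if method == "uniform":
        q = float(np.max(-np.diag(Q)))
        if q == 0:
            return np.zeros_like(Q)
        Pu = np.eye(Q.shape[0]) + Q / q
        lam = q * t
        from scipy.stats import poisson

        mmax = int(poisson.isf(1e-12, lam)) + 2
        J = np.zeros_like(Q, dtype=float)
        powers = [np.linalg.matrix_power(Pu, k) for k in range(mmax + 1)]
        w = poisson.pmf(np.arange(mmax + 1), lam)
        for m in range(1, mmax + 1):
            inner = np.zeros_like(Q, dtype=float)
            for k in range(m):
                inner += powers[k] @ (E / q) @ powers[m - 1 - k]
            J += w[m] * inner
        return J
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SubstitutionCounts:
    """Expected labelled substitution counts and rates for one lineage."""

    lineage: str
    n_sw: float
    n_ws: float
    n_neu: float
    L_GC: float
    L_AT: float

    @property
    def n_total(self) -> float:
        return self.n_sw + self.n_ws + self.n_neu

    @property
    def r_sw(self) -> float:
        return self.n_sw / self.L_GC

    @property
    def r_ws(self) -> float:
        return self.n_ws / self.L_AT

    @property
    def R(self) -> float:
        return self.r_sw / self.r_ws

    @property
    def ancestral_gc(self) -> float:
        return self.L_GC / (self.L_GC + self.L_AT)


def expected_substitution_counts(
    alignments, model: NonstationaryModel
) -> dict[str, SubstitutionCounts]:
    """Posterior-expected labelled substitution counts per branch.

    For each site pattern the joint posterior of the two internal node
    states is combined with the endpoint-conditional expected labelled event
    counts on every branch; ancestral L_GC / L_AT are posterior expectations
    of the relevant parent-node composition.
    """
    counts64 = (
        np.asarray(alignments, dtype=float)
        if np.ndim(alignments) == 1 and np.size(alignments) == 64
        else pattern_counts(*alignments)
    )
    P = {b: model.transition_matrix(b) for b in BRANCHES}
    Q = {b: model.rate_matrix(b) for b in BRANCHES}
    ts = model.branch_lengths
    # joint[r, x, a, b, c] over root state r, ancestor state x and leaves
    joint = np.einsum(
        "r,rx,rc,xa,xb->rxabc",
        model.root_pi,
        P["anc"],
        P["out"],
        P["in1"],
        P["in2"],
    )
    site_l = joint.sum(axis=(0, 1))  # (a, b, c)
    w = counts64.reshape(4, 4, 4)

    # endpoint-conditional expected labelled counts per branch and label
    cond = {}
    for b in BRANCHES:
        Pb = P[b]
        cond[b] = {}
        for lab, mask in LABELS.items():
            J = expected_labelled_counts(Q[b], ts[b], mask)
            with np.errstate(divide="ignore", invalid="ignore"):
                N = np.where(Pb > 0, J / Pb, 0.0)
            cond[b][lab] = N

    with np.errstate(divide="ignore", invalid="ignore"):
        wnorm = np.where(site_l > 0, w / site_l, 0.0)

    # posterior endpoint-pair weights per branch
    post_xa = np.einsum("rxabc,abc->xa", joint, wnorm)  # in1: (anc, leaf1)
    post_xb = np.einsum("rxabc,abc->xb", joint, wnorm)  # in2
    post_rx = np.einsum("rxabc,abc->rx", joint, wnorm)  # anc branch
    post_rc = np.einsum("rxabc,abc->rc", joint, wnorm)  # out branch
    pair_post = {"in1": post_xa, "in2": post_xb, "anc": post_rx, "out": post_rc}

    # posterior parent-state compositions
    anc_comp = post_xa.sum(axis=1)  # ancestor node composition
    root_comp = post_rx.sum(axis=1)
    parent_comp = {"in1": anc_comp, "in2": anc_comp, "anc": root_comp, "out": root_comp}

    out = {}
    for b in BRANCHES:
        nlab = {
            lab: float(np.sum(pair_post[b] * cond[b][lab])) for lab in LABELS
        }
        comp = parent_comp[b]
        L_GC = float(comp[_STRONG].sum())
        L_AT = float(comp[~_STRONG].sum())
        out[b] = SubstitutionCounts(
            lineage=b,
            n_sw=nlab["S>W"],
            n_ws=nlab["W>S"],
            n_neu=nlab["neutral"],
            L_GC=L_GC,
            L_AT=L_AT,
        )
    return out
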