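"""Probabilistic ancestral-allele inference with two outgroups.

For each SI site the ingroup sample (biallelic or monomorphic) is joined to
the alleles of two outgroup references on the fixed topology
((ingroup, outgroup1), outgroup2).  Branch-wise Kimura 2-parameter
substitution (transition and transversion amounts per branch; K2P matrices
commute, so the two basal branches collapse into one effective outgroup2
branch) is combined with a free unfolded-spectrum prior over derived-allele
counts, and both are estimated jointly by maximum likelihood (ECM: spectrum
by an EM step, branch parameters by bounded quasi-Newton).  The per-site
posterior probability that the major allele is ancestral is then used to
build probability-weighted class SFSs, matching est-sfs output semantics —
downstream models with polarization-error terms absorb any residual
misorientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .annotation import SiteRecord
from .sfs import CLASSES, ClassSFS, mutation_class

__all__ = [
    "OutgroupModel",
    "PolarizedSite",
    "fit_outgroup_model",
    "polarize",
    "build_class_sfs",
]

log = logging.getLogger(__name__)

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _a, _b in ((0, 2), (1, 3)):  # A<->G, C<->T
    _TRANSITION[_a, _b] = _TRANSITION[_b, _a] = True


def k2p_matrix(alpha_t: float, beta_t: float) -> np.ndarray:
    """K2P transition-probability matrix for transition amount ``alpha_t``
    and per-transversion amount ``beta_t`` (rate x time)."""
    e4 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * (alpha_t + beta_t))
    p_same = 0.25 + 0.25 * e4 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    P = np.full((4, 4), p_tv)
    P[_TRANSITION] = p_ts
    np.fill_diagonal(P, p_same)
    return P


@dataclass
class OutgroupModel:
    """Fitted branch parameters and spectrum prior."""

    branch_params: dict[str, tuple[float, float]]  # name -> (alpha_t, beta_t)
    spectrum: np.ndarray  # p_j over derived counts j = 0..n
    n: int
    loglik: float
    n_restarts: int
    restart_logliks: list[float] = field(default_factory=list)

    def transition_matrices(self) -> dict[str, np.ndarray]:
        return {k: k2p_matrix(*v) for k, v in self.branch_params.items()}


@dataclass
class PolarizedSite:
    site_id: str
    major: str
    minor: str | None
    n_minor: int  # copies of the minor allele (0 if monomorphic)
    p_major_ancestral: float
    class_if_major_ancestral: str | None  # mutation class, major->minor
    class_if_minor_ancestral: str | None


# ---------------------------------------------------------------------------


def _site_patterns(sites: list[SiteRecord], n: int):
    """Aggregate sites into unique (major, minor, j_minor, o1, o2) patterns."""
    patterns: dict[tuple, float] = {}
    order: list[tuple] = []
    site_keys = []
    for s in sites:
        col = s.ingroup_column
        if len(col) != n or any(c not in BASES for c in col):
            raise ValueError(
                f"site {s.intron_id}:{s.pos}: polymorphism mode requires a "
                f"complete ingroup column of length {n}"
            )
        alleles = sorted(set(col))
        if len(alleles) > 2:
            raise ValueError("sites with more than two ingroup alleles must be "
                             "removed before polarization")
        if len(alleles) == 1:
            maj, mnr, j = alleles[0], None, 0
        else:
            c0 = col.count(alleles[0])
            if c0 * 2 == n:
                maj, mnr = alleles[0], alleles[1]  # tie: alphabetical major
                j = n - c0
            elif c0 * 2 > n:
                maj, mnr, j = alleles[0], alleles[1], n - c0
            else:
                maj, mnr, j = alleles[1], alleles[0], c0
        # the second ingroup reference and the outgroup reference are the two
        # outgroup lineages of the polarization tree
        sp = [k for k in s.ref_allele]
        o1 = s.ref_allele[sp[1]] if len(sp) > 1 else s.ref_allele[sp[0]]
        o2 = s.outgroup_allele
        key = (maj, mnr, j, o1, o2)
        if key not in patterns:
            patterns[key] = 0.0
            order.append(key)
        patterns[key] += 1.0
        site_keys.append(key)
    weights = np.array([patterns[k] for k in order])
    return order, weights, site_keys


class _PatternIndex:
    """Static candidate-ancestor bookkeeping for a set of site patterns.

    Candidates: polymorphic -> [major, minor]; monomorphic -> [observed] +
    the three alternative ancestral bases (derived count n, spectrum mass
    p_n split uniformly across them).
    """

    def __init__(self, order, n):
        m = len(order)
        self.anc = np.zeros((m, 4), dtype=int)
        self.dc = np.zeros((m, 4), dtype=int)
        self.mask = np.zeros((m, 4), dtype=bool)
        self.prior_div = np.ones((m, 4))
        self.o1 = np.zeros(m, dtype=int)
        self.o2 = np.zeros(m, dtype=int)
        for i, (maj, mnr, j, o1, o2) in enumerate(order):
            self.o1[i], self.o2[i] = _IDX[o1], _IDX[o2]
            if mnr is not None:
                self.anc[i, 0], self.dc[i, 0] = _IDX[maj], j
                self.anc[i, 1], self.dc[i, 1] = _IDX[mnr], n - j
                self.mask[i, :2] = True
            else:
                self.anc[i, 0], self.dc[i, 0] = _IDX[maj], 0
                self.mask[i, 0] = True
                k = 1
                for b in range(4):
                    if BASES[b] == maj:
                        continue
                    self.anc[i, k], self.dc[i, k] = b, n
                    self.prior_div[i, k] = 3.0
                    self.mask[i, k] = True
                    k += 1

    def tree_factors(self, P_in, P_o1, P_o2) -> np.ndarray:
        # T[a, o1, o2] = 1/4 sum_x P_in[x,a] P_o1[x,o1] P_o2[x,o2]
        T = 0.25 * np.einsum("xa,xb,xc->abc", P_in, P_o1, P_o2)
        tf = T[self.anc, self.o1[:, None], self.o2[:, None]]
        tf[~self.mask] = 0.0
        return tf


def _loglik_and_resp(spectrum, tf, pidx, weights):
    pri = np.where(pidx.mask, spectrum[pidx.dc] / pidx.prior_div, 0.0)
    joint = pri * tf
    site_l = joint.sum(axis=1)
    if np.any(site_l <= 0):
        return -np.inf, None
    resp = joint / site_l[:, None]
    return float(np.sum(weights * np.log(site_l))), resp


def fit_outgroup_model(
    sites: list[SiteRecord],
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> OutgroupModel:
    """Joint ML fit of the K2P branch parameters and the spectrum prior."""
    n = len(sites[0].ingroup_column)
    if n < 2:
        raise ValueError("ingroup columns must contain at least two haplotypes")
    order, weights, _ = _site_patterns(sites, n)
    pidx = _PatternIndex(order, n)
    rng = np.random.default_rng(seed)

    def tf_for(z):
        mats = [k2p_matrix(np.exp(z[2 * k]), np.exp(z[2 * k + 1])) for k in range(3)]
        return pidx.tree_factors(*mats)

    def fit_once(z0):
        # z: log (alpha_t, beta_t) for (ingroup, outgroup1, outgroup2)
        spectrum = np.full(n + 1, 1.0 / (n + 1))
        z = z0.copy()
        prev = -np.inf
        for _ in range(max_iter):
            ll, resp = _loglik_and_resp(spectrum, tf_for(z), pidx, weights)
            if resp is None:
                return -np.inf, z, spectrum
            # EM update of the spectrum
            new_spec = np.zeros(n + 1)
            np.add.at(new_spec, pidx.dc[pidx.mask], (resp * weights[:, None])[pidx.mask])
            spectrum = new_spec / new_spec.sum()

            # conditional maximization over branch parameters
            def neg(zz):
                l2, _ = _loglik_and_resp(spectrum, tf_for(zz), pidx, weights)
                return -l2 if np.isfinite(l2) else 1e300

            res = minimize(neg, z, method="L-BFGS-B",
                           bounds=[(-12.0, 2.0)] * 6, options={"maxiter": 60})
            z = res.x
            ll = -res.fun
            if abs(ll - prev) < tol * (1.0 + abs(ll)):
                prev = ll
                break
            prev = ll
        return prev, z, spectrum

    best = None
    restart_lls = []
    for i in range(max(1, n_restarts)):
        if i == 0:
            z0 = np.log(np.full(6, 0.05))
        else:
            z0 = np.log(np.exp(rng.uniform(np.log(0.005), np.log(0.5), size=6)))
        ll, z, spec = fit_once(z0)
        restart_lls.append(ll)
        if best is None or ll > best[0]:
            best = (ll, z, spec)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError("outgroup model optimization failed in every restart")
    ll, z, spec = best
    names = ("ingroup", "outgroup1", "outgroup2")
    params = {
        names[k]: (float(np.exp(z[2 * k])), float(np.exp(z[2 * k + 1])))
        for k in range(3)
    }
    return OutgroupModel(
        branch_params=params,
        spectrum=spec,
        n=n,
        loglik=ll,
        n_restarts=max(1, n_restarts),
        restart_logliks=restart_lls,
    )


def polarize(sites: list[SiteRecord], model: OutgroupModel) -> list[PolarizedSite]:
    """Posterior probability that the major allele is ancestral, per site."""
    n = model.n
    order, weights, site_keys = _site_patterns(sites, n)
    pidx = _PatternIndex(order, n)
    mats = model.transition_matrices()
    tf = pidx.tree_factors(
        mats["ingroup"], mats["outgroup1"], mats["outgroup2"]
    )
    _, resp = _loglik_and_resp(model.spectrum, tf, pidx, weights)
    if resp is None:
        raise RuntimeError("model assigns zero likelihood to an observed pattern")
    by_key = {k: resp[i] for i, k in enumerate(order)}
    out = []
    for s, key in zip(sites, site_keys):
        maj, mnr, j, _, _ = key
        r = by_key[key]
        if mnr is None:
            p_major = float(r[0])
            cls_maj = cls_min = None
        else:
            p_major = float(r[0] / (r[0] + r[1])) if (r[0] + r[1]) > 0 else 0.5
            cls_maj = mutation_class(maj, mnr)
            cls_min = mutation_class(mnr, maj)
        sp = list(s.pos)
        out.append(
            PolarizedSite(
                site_id=f"{s.intron_id}@{s.pos[sp[0]]}",
                major=maj,
                minor=mnr,
                n_minor=j,
                p_major_ancestral=p_major,
                class_if_major_ancestral=cls_maj,
                class_if_minor_ancestral=cls_min,
            )
        )
    return out


def build_class_sfs(polarized: list[PolarizedSite], n: int) -> ClassSFS:
    """Probability-weighted class SFSs from polarized sites.

    A segregating site with minor count j contributes weight p (major
    ancestral) to its major-orientation class at derived count j and weight
    1 - p to the opposite orientation at derived count n - j, so total mass
    is conserved exactly.  Surveyed totals L_W / L_S accumulate monomorphic
    sites by their observed base and segregating sites by their posterior
    ancestral class.
    """
    xi = {c: np.zeros(n - 1) for c in CLASSES}
    L_W = L_S = 0.0
    strong = set("GC")
    for s in polarized:
        if s.minor is None:
            if s.major in strong:
                L_S += 1.0
            else:
                L_W += 1.0
            continue
        j = s.n_minor
        if not 1 <= j <= n - 1:
            raise ValueError(f"minor count {j} outside 1..n-1")
        p = s.p_major_ancestral
        xi[s.class_if_major_ancestral][j - 1] += p
        xi[s.class_if_minor_ancestral][n - j - 1] += 1.0 - p
        anc_strong = p * (s.major in strong) + (1.0 - p) * (s.minor in strong)
        L_S += anc_strong
        L_W += 1.0 - anc_strong
    return ClassSFS(n=n, xi=xi, L_W=L_W, L_S=L_S, n_sites=len(polarized))
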