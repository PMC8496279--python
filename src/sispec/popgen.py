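"""Diversity summaries, derived-allele-frequency diagnostics and the
equilibrium diversity predictor.

The singleton diagnostic uses the unfolded convention: the neutral
expectation of the proportion of segregating sites that are *derived*
singletons in a sample of n haploids is 1 / a_n with
a_n = sum_{i=1}^{n-1} 1/i, so the observed proportion divided by 1 / a_n
should be one for a constant-size neutral population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sfs import CLASSES, ClassSFS

__all__ = [
    "DiversitySummary",
    "DafSummary",
    "harmonic_number",
    "diversity_summary",
    "mean_daf",
    "relative_heterozygosity",
    "predict_relative_diversity",
    "expected_mutations_per_genome",
]


def harmonic_number(m: int) -> float:
    """H_m = sum_{i=1}^{m} 1/i by direct summation."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


@dataclass
class DiversitySummary:
    n: int
    n_sites: int
    n_segregating: int
    pi: float
    theta_w: float
    tajima_d: float
    prop_singletons: float
    singleton_ratio: float


@dataclass
class DafSummary:
    daf: dict[str, float]  # class -> mean derived allele frequency


def _pairwise_pi(counts: np.ndarray, n: int) -> float:
    """Average pairwise difference per site from minor-allele counts."""
    return float(np.sum(2.0 * counts * (n - counts) / (n * (n - 1))))


def diversity_summary(
    matrix: np.ndarray | list[str], n: int | None = None, sfs: ClassSFS | None = None
) -> DiversitySummary:
    """Standard diversity statistics for a haploid allele matrix.

    Parameters
    ----------
    matrix:
        Either an (n, L) array/list of sequences (rows = haplotypes) over
        A/C/G/T, or an (L,) integer array of derived/minor allele counts
        (then ``n`` is required).
    sfs:
        Optional class SFS used for the derived-singleton diagnostics; if
        absent, singleton counts fall back to minor-allele singletons.

    Notes
    -----
    pi is the average pairwise difference per site, theta_W = S / (a_n L),
    and Tajima's D uses the standard normalization.
    """
    if isinstance(matrix, (list, tuple)) or (
        isinstance(matrix, np.ndarray) and matrix.dtype.kind in "US"
    ):
        rows = ["".join(r) if not isinstance(r, str) else r for r in matrix]
        arr = np.array([list(r) for r in rows])
        n = arr.shape[0]
        L = arr.shape[1]
        counts = np.array(
            [np.sum(col != col[0]) if len(set(col)) > 1 else 0 for col in arr.T]
        )
        # recompute as true minor counts
        minor = []
        for col in arr.T:
            vals, cnt = np.unique(col, return_counts=True)
            if len(vals) == 1:
                minor.append(0)
            else:
                minor.append(int(np.sort(cnt)[:-1].sum()))
        counts = np.asarray(minor)
    else:
        counts = np.asarray(matrix, dtype=int)
        if n is None:
            raise ValueError("n is required when passing allele counts")
        L = counts.size
    if n < 2:
        raise ValueError("need at least two haplotypes")

    seg = counts[(counts > 0) & (counts < n)]
    S = seg.size
    a_n = harmonic_number(n - 1)
    pi = _pairwise_pi(seg, n) / L
    theta_w = S / (a_n * L)

    # Tajima's D with the standard constants
    if S > 0:
        a1 = a_n
        a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        var = e1 * S + e2 * S * (S - 1)
        tajima_d = (pi * L - S / a1) / np.sqrt(var) if var > 0 else 0.0
    else:
        tajima_d = 0.0

    if sfs is not None:
        n_seg = sfs.total_segregating()
        n_single = float(sum(sfs.xi[c][0] for c in CLASSES))
        prop = n_single / n_seg if n_seg > 0 else np.nan
    else:
        prop = float(np.sum(seg == 1) / S) if S > 0 else np.nan
    ratio = prop * a_n if np.isfinite(prop) else np.nan
    return DiversitySummary(
        n=n,
        n_sites=int(L),
        n_segregating=int(S),
        pi=float(pi),
        theta_w=float(theta_w),
        tajima_d=float(tajima_d),
        prop_singletons=float(prop),
        singleton_ratio=float(ratio),
    )


def mean_daf(sfs: ClassSFS) -> DafSummary:
    """Mean derived allele frequency per mutation class."""
    j = sfs.j
    daf = {}
    for c in CLASSES:
        total = sfs.xi[c].sum()
        daf[c] = float(np.sum(j * sfs.xi[c]) / (sfs.n * total)) if total > 0 else np.nan
    return DafSummary(daf=daf)


# ---------------------------------------------------------------------------
# equilibrium diversity prediction


def relative_heterozygosity(kappa: float, gamma: float) -> float:
    """Equilibrium heterozygosity under mutation-selection-drift, in units of
    2 * theta_WS (the low-mutation limit of the Wright stationary density):

        H(kappa, gamma) = kappa (e^gamma - 1) / (gamma (kappa + e^gamma))

    with the neutral limit kappa / (1 + kappa).  Derivable either from the
    stationary flux of new mutations weighted by their sojourn heterozygosity
    or as the theta -> 0 limit of E[2x(1-x)] under Wright's density.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if abs(gamma) < 1e-8:
        return kappa / (1.0 + kappa)
    return float(kappa * np.expm1(gamma) / (gamma * (kappa + np.exp(gamma))))


def wright_density_heterozygosity(
    kappa: float, gamma: float, theta: float = 1e-3, order: int = 120
) -> float:
    """E[2x(1-x)] under Wright's stationary density
    f(x) ~ e^{gamma x} x^{theta - 1} (1 - x)^{kappa theta - 1},
    normalized by 2 * theta; numeric-integration oracle for
    :func:`relative_heterozygosity` (agrees as theta -> 0).

    The integrable endpoint singularities are absorbed into a Gauss-Jacobi
    rule with weight exponents (kappa*theta - 1, theta - 1); only the smooth
    factor e^{gamma x} (times 2x(1-x) in the numerator) is sampled.
    """
    from scipy.special import roots_jacobi

    a, b = theta, kappa * theta
    t, w = roots_jacobi(order, b - 1.0, a - 1.0)
    x = 0.5 * (t + 1.0)
    smooth = np.exp(gamma * x)
    num = np.sum(w * smooth * 2.0 * x * (1.0 - x))
    den = np.sum(w * smooth)
    return num / den / (2.0 * theta)


def predict_relative_diversity(
    fit_a: tuple[float, float], fit_b: tuple[float, float]
) -> float:
    """Ratio of predicted equilibrium diversities for two (kappa, gamma)
    pairs, assuming equal mutation rate scale and effective population size."""
    ka, ga = fit_a
    kb, gb = fit_b
    return relative_heterozygosity(ka, ga) / relative_heterozygosity(kb, gb)


def expected_mutations_per_genome(
    rate_per_bp: float = 5e-9, genome_size_bp: float = 1.4e8
) -> float:
    """Expected new mutations per haploid genome per generation."""
    return rate_per_bp * genome_size_bp
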