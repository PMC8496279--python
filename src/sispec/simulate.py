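"""Synthetic polymorphism and divergence data with known ground truth.

Every downstream stage of the pipeline — polarization, SFS model fitting,
substitution counting — is exercised against data generated here with planted
parameters, so parameter recovery can be checked without any external data.

Three generators are provided:

``simulate_class_sfs``
    Draws the three class-specific unfolded SFSs as independent Poisson counts
    around the diffusion expectation, with demographic distortion and optional
    misorientation mixing.

``wright_fisher_oracle``
    A forward Wright-Fisher simulation of semidominant directional selection.
    It shares no code with the analytic expected SFS and serves as its
    independent oracle.

``simulate_triplet_alignment``
    Sequence evolution of short-intron sites along the rooted tree
    ((ingroup1, ingroup2), outgroup) under a nonstationary W/S-asymmetric
    substitution model, with a polymorphism overlay in the focal species and a
    per-branch truth table of labelled substitution events.

``write_synthetic_dataset`` materialises a triplet simulation as the on-disk
formats the pipeline consumes (genome FASTA + GFF3 per species, WGA-BED
columns, haplotype FASTA, truth tables), so the whole chain from annotation
parsing onward can be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .sfs import CLASSES, ClassSFS, mutation_class
from .sfs_model import expected_sfs, sfs_cell_means

__all__ = [
    "SimulationConfig",
    "TripletDataset",
    "simulate_class_sfs",
    "wright_fisher_oracle",
    "simulate_triplet_alignment",
    "concat_datasets",
    "write_synthetic_dataset",
]

BASES = "ACGT"
_STRONG_IDX = (1, 2)  # C, G
_WEAK_IDX = (0, 3)  # A, T
#: within-class partner used for GC-conservative changes
_NEUTRAL_PARTNER = {0: 3, 3: 0, 1: 2, 2: 1}

BRANCHES = ("in1", "in2", "anc", "out")


@dataclass
class SimulationConfig:
    """Ground-truth parameters and seed for the synthetic generators.

    Defaults mirror the study conditions: 9327 introns of 23 analyzed sites
    each, a haploid sample of n = 21, a strong-to-weak mutational bias of
    kappa ~ 2.8 and branch lengths close to the observed per-lineage
    divergences.  The class thetas are totals over all sites, scaled so that
    roughly 3% of sites segregate, comparable to the study's SNP density.
    """

    gamma: float = 0.0
    kappa: float = 2.8
    theta_ws: float = 3200.0
    theta_sw: float = 3000.0
    theta_neu: float = 2100.0
    n: int = 21
    distortion: np.ndarray | None = None  # r_j, j = 1..n-1
    polarization_error: float = 0.0
    n_introns: int = 9327
    intron_length: int = 23
    gc_distribution: np.ndarray | None = None  # per-intron root GC
    branch_lengths: dict[str, float] = field(
        default_factory=lambda: {"in1": 0.058, "in2": 0.066, "anc": 0.05, "out": 0.10}
    )
    branch_gc: dict[str, float] | None = None  # target GC per branch
    ts_tv: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.theta_ws, self.theta_sw, self.theta_neu) < 0:
            raise ValueError("theta values must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0.0 <= self.polarization_error < 0.5:
            raise ValueError("polarization_error must lie in [0, 0.5)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.n_introns < 1 or self.intron_length < 1:
            raise ValueError("n_introns and intron_length must be positive")
        if self.distortion is not None:
            self.distortion = np.asarray(self.distortion, dtype=float)
            if self.distortion.shape != (self.n - 1,):
                raise ValueError("distortion must have length n - 1")
            if np.any(self.distortion <= 0):
                raise ValueError("distortion entries must be > 0")
        if self.gc_distribution is not None:
            self.gc_distribution = np.asarray(self.gc_distribution, dtype=float)
            if self.gc_distribution.shape != (self.n_introns,):
                raise ValueError("gc_distribution must have length n_introns")
            if np.any((self.gc_distribution < 0) | (self.gc_distribution > 1)):
                raise ValueError("gc_distribution values must be in [0, 1]")
        for b in BRANCHES:
            if self.branch_lengths.get(b, 0.0) < 0:
                raise ValueError(f"branch length {b!r} must be >= 0")
        if self.ts_tv <= 0:
            raise ValueError("ts_tv must be > 0")

    @property
    def n_sites(self) -> int:
        return self.n_introns * self.intron_length

    def site_totals(self) -> tuple[float, float]:
        """(L_W, L_S) consistent with kappa and the class thetas.

        kappa = (theta_sw / L_S) / (theta_ws / L_W) fixes the ratio of the
        surveyed weak and strong totals; their sum is the number of sites.
        """
        ratio = self.kappa * self.theta_ws / self.theta_sw  # L_W / L_S
        L_S = self.n_sites / (1.0 + ratio)
        return self.n_sites - L_S, L_S

    def equilibrium_gc(self) -> float:
        return 1.0 / (1.0 + self.kappa * np.exp(-self.gamma))

    def root_gc(self, rng: np.random.Generator) -> np.ndarray:
        if self.gc_distribution is not None:
            return self.gc_distribution
        # spread of per-intron GC comparable to the observed SI range (~0.15-0.45)
        return rng.beta(5.0, 12.0, size=self.n_introns)

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# class-SFS generator


def simulate_class_sfs(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ClassSFS:
    """Poisson draw of the three class SFSs around the model expectation."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    means = sfs_cell_means(
        config.gamma,
        config.theta_ws,
        config.theta_sw,
        config.theta_neu,
        config.n,
        distortion=config.distortion,
        epsilon=config.polarization_error,
    )
    xi = {c: rng.poisson(means[c]).astype(float) for c in CLASSES}
    L_W, L_S = config.site_totals()
    return ClassSFS(n=config.n, xi=xi, L_W=L_W, L_S=L_S)


# ---------------------------------------------------------------------------
# Wright-Fisher oracle


def _wf_single(
    gamma: float,
    n: int,
    pop_size: int,
    reps: int,
    theta: float,
    rng: np.random.Generator,
    return_per_rep: bool = False,
):
    """Forward-simulate ``reps`` independent new mutations and return the
    accumulated empirical sample SFS (expected-count scale).

    Each replicate injects one copy of a mutant with scaled coefficient
    ``gamma`` into a population of ``pop_size`` haploids (genic selection with
    per-generation coefficient gamma / (2 * pop_size), the haploid equivalent
    of semidominant diploid selection with heterozygote advantage s/2) and
    follows it to absorption.  Every generation a sample of size ``n`` is
    drawn without replacement; segregating draws are histogrammed.  With a
    stationary mutational influx of theta/2 per generation the accumulated
    histogram estimates the expected unfolded SFS, so the result is scaled by
    theta / (2 * reps).
    """
    M = pop_size
    sigma = gamma / (2.0 * M)
    x = np.ones(reps, dtype=np.int64)  # mutant copy number per replicate
    idx = np.arange(reps)
    hist = np.zeros((reps, n - 1)) if return_per_rep else np.zeros(n - 1)
    guard = 0
    while idx.size:
        # sample without replacement from the current generation
        c = rng.hypergeometric(x, M - x, n)
        seg = (c >= 1) & (c <= n - 1)
        if np.any(seg):
            if return_per_rep:
                np.add.at(hist, (idx[seg], c[seg] - 1), 1.0)
            else:
                np.add.at(hist, c[seg] - 1, 1.0)
        # selection + binomial resampling
        f = x / M
        p = f * (1.0 + sigma) / (1.0 + sigma * f)
        x = rng.binomial(M, p)
        alive = (x > 0) & (x < M)
        x = x[alive]
        idx = idx[alive]
        guard += 1
        if guard > 500 * M:  # pragma: no cover - safety valve
            break
    # each replicate is one injected mutation; a stationary influx of theta/2
    # mutations per generation makes the per-replicate mean an estimate of the
    # expected SFS, so scale by theta / 2 (and average over replicates).
    if return_per_rep:
        return hist * (theta / 2.0)
    return hist * (theta / (2.0 * reps))


def wright_fisher_oracle(
    gamma: float,
    n: int,
    pop_size: int | None = None,
    reps: int = 100_000,
    seed: int | np.random.Generator | None = None,
    theta: float = 1.0,
    per_rep: bool = False,
):
    """Empirical class SFS from forward Wright-Fisher simulation.

    The W>S class is simulated with coefficient ``+gamma`` (GC favored), the
    S>W class with ``-gamma`` and the neutral class with 0; all three use the
    same ``theta``.  Returns a :class:`ClassSFS`; with ``per_rep=True``
    returns instead a dict class -> (reps, n-1) matrix of per-replicate
    contributions (in units of theta/2 per replicate), from which
    across-replicate standard errors can be formed.
    """
    if pop_size is None:
        pop_size = 50 * n
    if pop_size < n:
        raise ValueError("pop_size must be >= n")
    rng = np.random.default_rng(seed)
    if reps < 1000:
        import warnings

        warnings.warn("few replicates: the empirical SFS will be sparse")
    coeffs = {"W>S": gamma, "S>W": -gamma, "neutral": 0.0}
    if per_rep:
        return {
            c: _wf_single(g, n, pop_size, reps, theta, rng, return_per_rep=True)
            for c, g in coeffs.items()
        }
    xi = {c: _wf_single(g, n, pop_size, reps, theta, rng) for c, g in coeffs.items()}
    return ClassSFS(n=n, xi=xi, L_W=pop_size, L_S=pop_size, n_sites=2 * pop_size)


# ---------------------------------------------------------------------------
# triplet alignment simulator


def hky_rate_matrix(gc: float, ts_tv: float = 2.0) -> np.ndarray:
    """HKY-style rate matrix with target GC ``gc``, normalized so that the
    expected rate at the target composition is one substitution per site."""
    if not 0.0 < gc < 1.0:
        raise ValueError("target GC must be in (0, 1)")
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    s = np.ones((4, 4))
    s[0, 2] = s[2, 0] = ts_tv  # A<->G
    s[1, 3] = s[3, 1] = ts_tv  # C<->T
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(pi * np.diag(Q))
    return Q / mu


def _draw_categorical(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw per row of the row-stochastic matrix ``P``."""
    u = rng.random(P.shape[0])
    return (P.cumsum(axis=1) < u[:, None]).sum(axis=1)


def _evolve_branch(states: np.ndarray, G: np.ndarray, rng: np.random.Generator):
    """Gillespie simulation of the CTMC with generator ``G`` over unit time.

    Returns the final states and arrays (site, from, to) of every event, so
    true substitution counts (including multiple hits) are known exactly.
    """
    s = states.copy()
    t = np.zeros(s.shape, dtype=float)
    active = np.flatnonzero(np.ones_like(s, dtype=bool))
    ev_site, ev_from, ev_to = [], [], []
    while active.size:
        lam = -G[s[active], s[active]]
        movable = lam > 0
        active = active[movable]
        lam = lam[movable]
        if active.size == 0:
            break
        t[active] += rng.exponential(1.0 / lam)
        jumping = active[t[active] < 1.0]
        if jumping.size:
            cur = s[jumping]
            P = G[cur, :].copy()
            P[np.arange(jumping.size), cur] = 0.0
            P /= P.sum(axis=1, keepdims=True)
            new = _draw_categorical(P, rng)
            ev_site.append(jumping)
            ev_from.append(cur)
            ev_to.append(new.astype(cur.dtype))
            s[jumping] = new
        active = jumping
    if ev_site:
        return s, np.concatenate(ev_site), np.concatenate(ev_from), np.concatenate(ev_to)
    empty = np.array([], dtype=int)
    return s, empty, empty, empty


def _label_of(frm: np.ndarray, to: np.ndarray) -> np.ndarray:
    """0 = S>W, 1 = W>S, 2 = neutral, matching CLASSES order."""
    f_strong = np.isin(frm, _STRONG_IDX)
    t_strong = np.isin(to, _STRONG_IDX)
    lab = np.full(frm.shape, 2)
    lab[f_strong & ~t_strong] = 0
    lab[~f_strong & t_strong] = 1
    return lab


@dataclass
class TripletDataset:
    """A simulated three-species dataset with per-branch ground truth."""

    config: SimulationConfig
    refs: dict[str, np.ndarray]  # species -> (n_introns, L) int state arrays
    haplotypes: np.ndarray  # (n, n_introns, L) focal-species sample states
    truth: pd.DataFrame  # per intron x branch labelled event counts
    poly: pd.DataFrame  # polymorphic-site table for the focal species
    sfs: ClassSFS  # the class SFS actually planted

    def ref_sequence(self, species: str, intron: int) -> str:
        return "".join(BASES[b] for b in self.refs[species][intron])

    def haplotype_sequence(self, hap: int, intron: int) -> str:
        return "".join(BASES[b] for b in self.haplotypes[hap, intron])


def simulate_triplet_alignment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TripletDataset:
    """Evolve short-intron sites along ((in1, in2), out) and overlay
    polymorphism in the focal species ``in1``.

    The substitution process is branch-wise homogeneous but nonstationary:
    each branch has its own target GC (default: the equilibrium GC implied by
    the planted kappa and gamma) while the root composition follows the
    per-intron GC distribution.  A site carrying a polymorphism replaces any
    fixed difference at that site (the ingroup haplotypes segregate around
    the ingroup reference state), so a site is either polymorphic or fixed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_int, L = config.n_introns, config.intron_length
    total = n_int * L
    root_gc = np.repeat(config.root_gc(rng), L)
    # root sequence: per-site composition set by the intron's root GC
    pvec = np.stack(
        [(1 - root_gc) / 2, root_gc / 2, root_gc / 2, (1 - root_gc) / 2], axis=1
    )
    root = _draw_categorical(pvec, rng)

    gc_eq = float(config.equilibrium_gc())
    branch_gc = config.branch_gc or {b: gc_eq for b in BRANCHES}
    site_intron = np.repeat(np.arange(n_int), L)

    truth_rows = []
    states = {"root": root}
    parents = {"anc": "root", "out": "root", "in1": "anc", "in2": "anc"}
    for b in ("anc", "out", "in1", "in2"):
        t_b = config.branch_lengths.get(b, 0.0)
        Q = hky_rate_matrix(branch_gc[b], config.ts_tv)
        end, site, frm, to = _evolve_branch(states[parents[b]], Q * t_b, rng)
        states[b] = end
        lab = _label_of(frm, to)
        counts = np.zeros((n_int, 3), dtype=int)
        if site.size:
            np.add.at(counts, (site_intron[site], lab), 1)
        for i in range(n_int):
            truth_rows.append(
                {
                    "intron": i,
                    "branch": b,
                    "n_SW": counts[i, 0],
                    "n_WS": counts[i, 1],
                    "n_neu": counts[i, 2],
                    "n_total": int(counts[i].sum()),
                }
            )
        if b == "in1":
            in1_events = np.unique(site)
    truth = pd.DataFrame(truth_rows)

    # ---- polymorphism overlay in the focal species ----
    # The config thetas define *per-site* mutational inputs at the nominal
    # composition; the planted class totals scale with the realized ancestral
    # (ingroup reference) composition so that kappa is recoverable from the
    # alignment exactly as from SFS-level data.
    in1_states = states["in1"]
    n_strong_real = int(np.isin(in1_states, _STRONG_IDX).sum())
    n_weak_real = total - n_strong_real
    L_W_cfg, L_S_cfg = config.site_totals()
    v_rate = config.theta_ws / L_W_cfg  # weak -> strong input per weak site
    means = sfs_cell_means(
        config.gamma,
        v_rate * n_weak_real,
        config.kappa * v_rate * n_strong_real,
        config.theta_neu,
        config.n,
        distortion=config.distortion,
        epsilon=0.0,
    )
    counts = {c: rng.poisson(means[c]) for c in CLASSES}
    in1 = states["in1"]
    eligible = np.ones(total, dtype=bool)
    eligible[in1_events] = False  # never stack a polymorphism on a fixed difference
    strong_pool = np.flatnonzero(eligible & np.isin(in1, _STRONG_IDX))
    weak_pool = np.flatnonzero(eligible & np.isin(in1, _WEAK_IDX))
    rng.shuffle(strong_pool)
    rng.shuffle(weak_pool)
    pools = {"S>W": strong_pool, "W>S": weak_pool}
    cursors = {"S>W": 0, "W>S": 0}

    hap = np.broadcast_to(in1, (config.n, total)).copy()
    poly_rows = []
    for cls in CLASSES:
        for j0, m in enumerate(counts[cls]):
            j = j0 + 1
            for _ in range(int(m)):
                if cls == "neutral":
                    # strong vs weak host drawn by the eligible composition
                    p_strong = strong_pool.size / max(strong_pool.size + weak_pool.size, 1)
                    pool_name = "S>W" if rng.random() < p_strong else "W>S"
                else:
                    pool_name = cls
                pool = pools[pool_name]
                k = cursors[pool_name]
                if k >= pool.size:
                    import warnings

                    warnings.warn(
                        f"ran out of eligible sites for class {cls}; clipping"
                    )
                    break
                cursors[pool_name] = k + 1
                g = pool[k]
                anc = int(in1[g])
                if cls == "neutral":
                    der = _NEUTRAL_PARTNER[anc]
                elif cls == "S>W":
                    der = int(rng.choice(_WEAK_IDX))
                else:
                    der = int(rng.choice(_STRONG_IDX))
                carriers = rng.choice(config.n, size=j, replace=False)
                hap[carriers, g] = der
                poly_rows.append(
                    {
                        "intron": int(site_intron[g]),
                        "offset": int(g % L),
                        "site": int(g),
                        "ancestral": BASES[anc],
                        "derived": BASES[der],
                        "count": j,
                        "class": mutation_class(BASES[anc], BASES[der]),
                        "carriers": tuple(int(c) for c in sorted(carriers)),
                    }
                )

    xi = {c: np.zeros(config.n - 1) for c in CLASSES}
    poly = pd.DataFrame(
        poly_rows,
        columns=[
            "intron",
            "offset",
            "site",
            "ancestral",
            "derived",
            "count",
            "class",
            "carriers",
        ],
    )
    for _, row in poly.iterrows():
        xi[row["class"]][row["count"] - 1] += 1
    n_strong = int(np.isin(in1, _STRONG_IDX).sum())
    planted = ClassSFS(
        n=config.n, xi=xi, L_W=total - n_strong, L_S=n_strong, n_sites=total
    )

    refs = {sp: states[sp].reshape(n_int, L) for sp in ("in1", "in2", "out")}
    return TripletDataset(
        config=config,
        refs=refs,
        haplotypes=hap.reshape(config.n, n_int, L),
        truth=truth,
        poly=poly,
        sfs=planted,
    )


def concat_datasets(datasets: list[TripletDataset]) -> TripletDataset:
    """Concatenate triplet simulations along the intron axis.

    Used to build datasets in which the planted parameters vary across
    GC strata (e.g. a gamma gradient); all inputs must share n, intron
    length and branch lengths.  The merged config echoes the first input
    with the summed intron count.
    """
    import dataclasses as _dc

    first = datasets[0].config
    for d in datasets[1:]:
        if d.config.n != first.n or d.config.intron_length != first.intron_length:
            raise ValueError("datasets must share n and intron_length")
    offs_introns = np.cumsum([0] + [d.config.n_introns for d in datasets])
    offs_sites = offs_introns * first.intron_length
    refs = {
        sp: np.concatenate([d.refs[sp] for d in datasets], axis=0)
        for sp in datasets[0].refs
    }
    hap = np.concatenate([d.haplotypes for d in datasets], axis=1)
    truth_parts, poly_parts = [], []
    for k, d in enumerate(datasets):
        t = d.truth.copy()
        t["intron"] += offs_introns[k]
        truth_parts.append(t)
        p = d.poly.copy()
        p["intron"] += offs_introns[k]
        p["site"] += offs_sites[k]
        poly_parts.append(p)
    xi = {
        c: np.sum([d.sfs.xi[c] for d in datasets], axis=0) for c in CLASSES
    }
    L_W = sum(d.sfs.L_W for d in datasets)
    L_S = sum(d.sfs.L_S for d in datasets)
    cfg = _dc.replace(
        first,
        n_introns=int(offs_introns[-1]),
        gc_distribution=None,
        distortion=first.distortion,
    )
    return TripletDataset(
        config=cfg,
        refs=refs,
        haplotypes=hap,
        truth=pd.concat(truth_parts, ignore_index=True),
        poly=pd.concat(poly_parts, ignore_index=True),
        sfs=ClassSFS(n=first.n, xi=xi, L_W=L_W, L_S=L_S, n_sites=L_W + L_S),
    )


# ---------------------------------------------------------------------------
# on-disk dataset


_INTRON_5P = "GTAAGTA"  # 7 bp: splice donor + spacer, positions 1-7
_EXON_LEN = 30
_SPACER_LEN = 20
_INTRON_3P_LEN = 35  # positions 31-65, ends with the splice acceptor AG


def _random_filler(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


def write_synthetic_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    dataset: TripletDataset | None = None,
) -> dict[str, Path]:
    """Write a triplet simulation in the pipeline's input formats.

    Produces, per species (``A`` = focal ingroup, ``B`` = second ingroup), a
    genome FASTA and a GFF3 with two-exon genes whose single 65-bp intron
    carries the simulated 23 SI sites at positions 8-30; a WGA-BED file with
    one column per SI site (coordinates + alleles in A, B and the outgroup);
    a multi-FASTA of the focal species' haplotypes; the truth tables; and a
    JSON echo of the configuration.  All coordinates 0-based half-open.
    """
    if config.intron_length != 23:
        raise ValueError("the on-disk layout requires intron_length == 23")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        dataset = simulate_triplet_alignment(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD15C]))

    n_int = config.n_introns
    unit = _EXON_LEN + 7 + 23 + _INTRON_3P_LEN + _EXON_LEN + _SPACER_LEN
    chrom = "2R"

    fillers = []
    for i in range(n_int):
        fillers.append(
            {
                "exon1": _random_filler(_EXON_LEN, rng),
                "intron3p": _random_filler(_INTRON_3P_LEN - 2, rng) + "AG",
                "exon2": _random_filler(_EXON_LEN, rng),
                "spacer": _random_filler(_SPACER_LEN, rng),
            }
        )

    def genome_for(seqs_by_intron) -> str:
        parts = []
        for i in range(n_int):
            f = fillers[i]
            parts.append(
                f["exon1"] + _INTRON_5P + seqs_by_intron(i) + f["intron3p"] + f["exon2"] + f["spacer"]
            )
        return "".join(parts)

    paths: dict[str, Path] = {}
    for sp, key in (("A", "in1"), ("B", "in2")):
        seq = genome_for(lambda i, k=key: "".join(BASES[b] for b in dataset.refs[k][i]))
        fa = outdir / f"genome_{sp}.fa"
        with open(fa, "w") as fh:
            fh.write(f">{chrom}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")
        paths[f"genome_{sp}"] = fa

        gff = outdir / f"annotation_{sp}.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for i in range(n_int):
                off = i * unit
                gene_start = off + 1  # GFF3 is 1-based inclusive
                e1s, e1e = gene_start, off + _EXON_LEN
                e2s = off + _EXON_LEN + 65 + 1
                e2e = e2s + _EXON_LEN - 1
                gid = f"gene{i}"
                fh.write(
                    f"{chrom}\tsispec\tgene\t{e1s}\t{e2e}\t.\t+\t.\tID={gid}\n"
                    f"{chrom}\tsispec\tmRNA\t{e1s}\t{e2e}\t.\t+\t.\tID={gid}.t1;Parent={gid}\n"
                    f"{chrom}\tsispec\texon\t{e1s}\t{e1e}\t.\t+\t.\tID={gid}.e1;Parent={gid}.t1\n"
                    f"{chrom}\tsispec\texon\t{e2s}\t{e2e}\t.\t+\t.\tID={gid}.e2;Parent={gid}.t1\n"
                )
        paths[f"annotation_{sp}"] = gff

    # WGA-BED: one row per SI site; both species share coordinates by design
    wga = outdir / "alignment.wga.bed"
    with open(wga, "w") as fh:
        for i in range(n_int):
            si0 = i * unit + _EXON_LEN + 7  # 0-based start of the 23 SI sites
            for k in range(23):
                pos = si0 + k
                a = BASES[dataset.refs["in1"][i, k]]
                b = BASES[dataset.refs["in2"][i, k]]
                o = BASES[dataset.refs["out"][i, k]]
                fh.write(
                    f"{chrom}\t{pos}\t{pos + 1}\t+\t{a}\t"
                    f"{chrom}\t{pos}\t{pos + 1}\t+\t{b}\t{o}\n"
                )
    paths["wga"] = wga

    # focal-species haplotypes (genome-wide, polymorphism only at SI sites)
    hap_fa = outdir / "haplotypes_A.fa"
    with open(hap_fa, "w") as fh:
        for h in range(config.n):
            seq = genome_for(
                lambda i, h=h: "".join(BASES[b] for b in dataset.haplotypes[h, i])
            )
            fh.write(f">hap{h}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")
    paths["haplotypes"] = hap_fa

    dataset.truth.to_csv(outdir / "truth_branches.tsv", sep="\t", index=False)
    dataset.poly.drop(columns=["carriers"]).to_csv(
        outdir / "truth_polymorphism.tsv", sep="\t", index=False
    )
    (outdir / "config.json").write_text(config.to_json())
    paths["truth"] = outdir / "truth_branches.tsv"
    paths["config"] = outdir / "config.json"
    return paths
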