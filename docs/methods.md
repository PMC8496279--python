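# Methods

This note documents the models, the numerical choices and the synthetic-data
conditions behind `sispec`, and states what passing tests do and do not
establish about real data.

## The expected SFS under a semidominant directional force

For a new mutation favored with scaled coefficient γ = 4·N·s (semidominant:
heterozygote advantage s/2), the diffusion sojourn density of the derived
allele, weighted by binomial sampling into n haploids, gives the expected
unfolded spectrum

E[ξ_j] = θ · C(n,j) · ∫₀¹ u(γ,x) x^j (1−x)^{n−j} dx,
u(γ,x) = (1 − e^{−γ(1−x)}) / ((1 − e^{−γ}) x(1−x)),

normalized so that the neutral limit is exactly θ/j. The W>S class uses +γ,
S>W uses −γ, and the GC-conservative class (A↔T, C↔G) is neutral. Useful
identities used as test oracles:

- reflection: E[ξ_j; −γ] + E[ξ_{n−j}; +γ] = θ·n/(j(n−j));
- γ → 0 continuity, handled by a second-order expansion below |γ| = 10⁻⁶.

Numerics: fixed-order Gauss–Legendre (order 64) on (0,1). After cancelling
the x(1−x) endpoint singularities against the binomial kernel the integrand
is smooth, and order 64 agrees with adaptive quadrature to ~10⁻¹⁰ relative
for n up to 69 and |γ| ≤ 50; |γ| > 50 is rejected rather than risk overflow.

## The nested Poisson models (M0, M0*, M1, M1*)

Observed class SFS cells are independent Poissons. Cell means are
r_j · E[ξ_j; γ_class, θ_class], with one distortion vector r_j (j = 2..n−1,
r₁ ≡ 1 for identifiability — doubling r while halving θ leaves every mean
unchanged) shared across the three classes: demography distorts all classes
alike, a directional force does not, which is what makes γ identifiable
without assuming demographic equilibrium. The starred models add a
misorientation probability ε: the distorted true spectrum of each class is
mixed with the frequency-reflected spectrum of its opposite class
(mean*_c,j = (1−ε)·r_j·E_c,j + ε·r_{n−j}·E_opp,n−j; neutral is its own
opposite). One shared ε per fit by default; the error acts on the true
(distorted) frequencies because misorientation happens at inference, after
drift has acted. κ is never a free parameter: it is derived as
(θ_SW/L_S)/(θ_WS/L_W) from the fitted class inputs and the surveyed
ancestral-state totals.

Fitting: L-BFGS-B on log-transformed positive parameters (γ bounded in
[−25, 25], ε in [0, 0.499]), method-of-moments starting thetas
(class total / a_n), seed-controlled jittered multi-starts (default 10).
LRTs use χ² with df equal to the parameter-count difference; the γ = 0 null
is interior (γ may be negative), so the standard χ²₁ reference applies to
M0-vs-M1, and its calibration is verified by simulation in the acceptance
suite.

Surveyed totals L_W/L_S count monomorphic sites by their observed base plus
segregating sites by their posterior ancestral class; mass conservation
(Σξ + monomorphic = sites analyzed) is asserted separately. At SI-site
polymorphism densities the distinction from a monomorphic-only convention is
negligible, but the inclusive convention is the one under which κ is exactly
the mutational-input ratio.

## Polarization

The ancestral allele of each biallelic or monomorphic ingroup site is
inferred from two outgroup references on the fixed topology
((ingroup, outgroup1), outgroup2). Each branch carries Kimura 2-parameter
transition/transversion amounts; K2P matrices commute, so the two basal
branches collapse into an effective outgroup2 distance and three branch
parameter pairs suffice. A free spectrum prior p_j over derived counts
j = 0..n (monomorphic sites may be ancestrally different from their observed
base; that p_n mass is split uniformly over the three alternatives) is
estimated jointly with the branch parameters by ECM: an EM step for the
spectrum, bounded quasi-Newton for the branches, iterated to a 10⁻⁸
relative tolerance, best of multiple jittered restarts. Downstream SFSs are
probability-weighted (each segregating site contributes p to one orientation
and 1−p to the reflected opposite class), matching est-sfs semantics;
residual misorientation is the business of the starred models, not of a hard
threshold at p = 0.5.

## Divergence and expected Markov counting

The three-taxon model is GTR-style with shared exchangeabilities (6, one
pinned), a free root composition and free per-branch target compositions —
fully free per branch, the least-committed reading of a branch-nonstationary
model (nonstationary models are root-identifiable, so the root composition
is estimable). Branch rate matrices are normalized to one expected
substitution per site at their own target composition, so branch lengths are
expected substitutions per site at the target. The stationary GTR (all
compositions tied) is fitted to the same pattern counts for a df = 12 LRT.

Labelled substitution counts use the closed form for the expected number of
i→j events of a CTMC on (0,t) joint with the endpoint states: with
Q = UΛU⁻¹ and E the label-masked rate matrix,
J = U[(U⁻¹EU) ∘ Φ]U⁻¹, Φ_kl = (e^{λ_k t} − e^{λ_l t})/(λ_k − λ_l)
(t·e^{λt} on ties); conditioning divides by the transition probability.
If the eigenvector matrix is ill-conditioned (cond > 10⁸) the code falls
back to uniformization with the Poisson series truncated at tail mass
10⁻¹², and the two routes are asserted equal on random generators in the
unit tests. Per-site posteriors over the two internal node states weight the
endpoint-conditional expectations, and ancestral GC/AT totals are posterior
expectations — no single ancestral sequence is committed to anywhere.

Equilibrium algebra: GC* = 1/(1+κe^{−γ}); γ*(GC,κ) = −ln[(1−GC)/(GC·κ)];
R = κe^{−γ}; required κ at neutrality = (1−GC)/GC. The Pearson 1:1 test on
(N_W>S, N_S>W) uses no continuity correction, the convention that reproduces
the printed statistics from printed counts.

## Equilibrium diversity prediction

The predicted equilibrium heterozygosity at a (κ, γ) site class, in the
low-mutation limit and up to a shared 2θ scale, is

H(κ, γ) = κ(e^γ − 1) / (γ(κ + e^γ)),

with neutral limit κ/(1+κ). Two independent derivations agree: (i) the
stationary flux argument — fraction of sites ancestrally W is
κe^{−γ}/(1+κe^{−γ}), each new mutation contributes sojourn heterozygosity
2[1/(1−e^{−γ}) − 1/γ]; (ii) the θ→0 limit of E[2x(1−x)] under Wright's
density e^{γx}x^{θ−1}(1−x)^{κθ−1}, evaluated in the tests by Gauss–Jacobi
quadrature (which absorbs the endpoint singularities into the weight) and
required to agree with the closed form to 3 significant figures.

A consequence worth stating: H is *not* monotone in |γ| when κ ≠ 1. For
κ > 1 a weak GC-favoring force initially raises diversity, because it shifts
the composition toward the faster-mutating strong class and favored
mutations spend more sojourn time at intermediate frequencies; only for
κ = 1 does a directional force of either sign strictly remove variation
(H(1,γ) = tanh(γ/2)/γ). The monotonicity property test is therefore run at
κ = 1.

## Synthetic data: what it emulates and what it does not

The generator's defaults mirror the study conditions: 9327 introns × 23
analyzed sites, haploid samples n ∈ {21, 69}, κ ≈ 2.8, branch lengths near
the observed per-lineage divergences (0.058/0.066 for the two ingroup
branches), and class mutational inputs scaled so roughly 3% of sites
segregate. Per-intron root GC follows Beta(5,12) (mean 0.29, sd ≈ 0.10,
matching the observed SI spread) unless given explicitly.

`simulate_class_sfs` draws Poisson counts around the model's own cell means
(distortion, then ε-mixing) — by construction the correctly specified case.
`simulate_triplet_alignment` is the stronger test bed: Gillespie simulation
of an HKY-style chain with branch-specific target GC along
((in1,in2),out), exact per-branch event labels (multiple hits included), and
a polymorphism overlay in the focal species whose class totals scale with
the *realized* ancestral composition (so κ is recoverable from alignments
exactly as from SFS-level data). Overlay sites are drawn only where no
substitution occurred on the focal branch: a site is polymorphic or fixed,
never both. The Wright–Fisher oracle simulates genic selection with
per-generation coefficient γ/(2M) in M = 50n haploids — the haploid
equivalent of semidominant diploid selection — injecting single-copy
mutants and accumulating without-replacement samples every generation; with
influx θ/2 per generation its histogram estimates the expected SFS on the
same scale as the analytic form. Its agreement test uses per-trajectory
standard errors (trajectory contributions are i.i.d.; within-trajectory
generations are not), with a 2% allowance for the O(1/M) discreteness of
the WF model relative to the diffusion.

Not emulated: recombination and linkage (each site evolves independently),
indels, base-composition context effects, chromosome structure, missing
data and sequencing error. Passing tests therefore demonstrate correctness
of the inference machinery under the model's own assumptions and robustness
to demographic distortion and misorientation — not robustness to alignment
error or linked selection in real data.

## Problem sizes and tolerances in the test suite

Simulation sizes were chosen by power analysis at desk scale: parameter
recovery uses ~200 synthetic SFS datasets over a 3×3 (γ, κ) grid at
study-scale thetas, where the per-dataset sampling error of γ̂ is ~0.1, so
the pooled median-bias thresholds (0.05 on γ, 2.5% on κ) sit well above the
Monte-Carlo error of the median while still detecting real bias. LRT
calibration uses 200 null replicates with a ±3-binomial-SE acceptance band
around 5%. The end-to-end gradient run plants γ = (−2,−1,0,1,2) across five
GC strata of 300 introns each, spacing chosen so that monotone recovery has
a comfortable margin over the per-bin γ̂ standard error (~0.3); the
polarization-then-fit route attenuates extreme γ̂ slightly toward zero
(posterior weighting smooths the class spectra), which compresses but never
reorders the gradient. Path-simulation checks of Markov counting use ~10⁶
paths and assert agreement within max(4 MC standard errors, 3 significant
figures). Degenerate inputs (all-N sequences, empty SFS classes, zero
branch lengths, boundary GC values) raise errors or return defined limits
as documented per function; binning ties break by intron id so every run is
deterministic.

## Known limitations

- One focal population per pipeline run; the two-population comparison of
  the study corresponds to two runs with roles swapped.
- The haplotype FASTA convention assumes single-chromosome coordinates (one
  record per haplotype).
- The polarization model is K2P-only, as a 6-parameter model was found
  unnecessary for these species; the interface would admit richer models
  but none are implemented.
- Bootstrap CIs in the pipeline cover the cheap per-bin statistics; a full
  bootstrap of the likelihood fits is available through `bootstrap_ci` but
  is not run by default at 1000 replicates.
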