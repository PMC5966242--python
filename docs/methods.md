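# Methods

## Model overview

A culture's population dynamics are summarised as a piecewise profile: CFU
counts N₀ … N_K at sampling timepoints and one relative death rate d_k
(deaths per division event, dimensionless) per interval. d < 1 means net
growth, d > 1 net decline, d = 0 the classical no-death regime. Because
mutation is modelled per division — not per unit time — all inference
depends on the profile only through its sizes and death rates; wall-clock
interval durations are internal bookkeeping. The number of division events
an interval requires is B_k = ΔN_k / (1 − d_k).

Mutants are assumed neutral (same birth and death rates as wild type),
double and back mutation are neglected (μ ≪ 1), cells are monoploid with
one chromosome, and the population is homogeneous — no subpopulation
carries a distinct death or mutation rate. Mutagenesis in non-dividing
cells is outside the model, so the method does not apply to starving,
spatially structured populations.

## Death rates from plasmid segregation

A plasmid whose replication requires an inducer dilutes at cell division
once the inducer is removed. With residual replication `res` (plasmid
replications per cell division, res ∈ [0, 1)), the plasmid-bearing
fraction obeys F_final = F_initial · ((1+res)/2)^g over g generations, so

    g = log₂(F_final / F_initial) / σ,      σ = log₂((1+res)/2)

and, comparing with the generations implied by the net size change,

    d = 1 − log₂(N_final / N_initial) / g.

**Fitting σ.** Untreated cultures are assumed death-free, so their
generations equal log₂ fold-growth. log₂ F is regressed on cumulative log₂
fold-growth with the intercept anchored at log₂ F(t₀), jointly across all
untreated intervals and replicates — a single least-squares slope uses all
the data and is robust to one noisy plate. A fitted σ below −1 (possible
under plating noise; retention cannot beat pure dilution) is clamped to
σ = −1, i.e. res = 0. Whether σ is refit per batch or fixed globally is the
caller's choice; the packaged studies refit per batch.

**Clamping and capping d.** Negative raw d (a treated culture apparently
dying less than the untreated reference) can only arise from measurement
noise; it is clamped to 0 — conservative in the sense that it can only
under-correct the mutation rate, never inflate the correction. Raw values
above a cap (default 5) are set to the cap: at extreme death the estimate
of g, a ratio of two logarithms, becomes noise-dominated and an unbounded d
would dominate downstream division counts. Both raw and processed values
are reported per interval, along with flags. When assembling a profile,
inverted death rates are nudged across the d = 1 boundary where needed to
restore sign consistency with the observed size change (flagged as clamped).

**Error model.** Each CFU measurement is a colony count at some dilution;
the fixture generator and the noise studies use Poisson counts at ~300
colonies per plate, with total and plasmid-bearing plates at independent
dilutions. Under this noise the single-interval inversion at true d = 0.5
has a median absolute error well below 0.01 at desk scale; the acceptance
threshold of 0.25 is generous.

## Simulating mutant counts under arbitrary dynamics

**Hybrid clone-based algorithm (production).** The wild type follows the
profile deterministically. Within interval k, per-capita birth rate is
fixed at 1, the death/birth ratio is d_k, and the interval's internal
duration is solved from N(t) = N_k·exp((1−d_k)t) hitting N_{k+1} — a pure
parameterisation choice; a test asserts results are invariant to stretching
the time axis. Mutational events arrive as Poisson(μ·B_k), each placed
uniformly over the interval's divisions (uniform in net size change, not in
wall-clock time). Each event seeds one cell that evolves as a linear
birth–death process with the prevailing rates, through the remainder of its
interval and all subsequent intervals. The descendant count after time t of
one cell under birth rate 1 and death rate d is 0 with probability p₀ and
otherwise geometric; with w = e^{(1−d)t},

    p₀ = d(w − 1)/(w − d),   P(Z = j | Z > 0) = (1 − p_b) p_b^{j−1},
    p_b = (w − 1)/(w − d)        (p₀ = p_b = t/(1+t) when d = 1),

so clones propagate in O(1) per interval via binomial survivors plus a
negative-binomial excess, vectorised across clones and cultures. Declining
intervals (d > 1) use the same formulas (subcritical). Plating is exact
binomial thinning of each culture's final mutant number.

The deterministic-wild-type assumption requires per-interval divisions
B_k ≫ 1; the validation suite therefore compares against the oracle on
instances of tens to hundreds of cells, where the approximation is at its
weakest, and still finds pooled-bin total-variation distances below 0.02.
At very small populations combined with extreme turnover (e.g. 5 cells at
d = 0.9) the conditioning of the true process on non-extinction becomes
visible and the hybrid algorithm slightly overestimates mutant numbers;
real assays operate many orders of magnitude away from this corner.

**Gillespie-style oracle (validation).** For small instances every single
division and death is simulated: per interval, B_k division and B_k − ΔN_k
death events are interleaved uniformly at random conditioned on
non-extinction (rejection sampling), each event hits a uniformly chosen
cell, and each wild-type division mutates a daughter with probability μ.
Conservation (divisions − deaths = ΔN) holds exactly on every run. The
oracle is guarded to final sizes ≤ 1e5.

**Intervals with d = 1.** A constant population size at d = 1 is
compatible with any amount of turnover; the pair (sizes, d) does not
identify it. Such intervals are assigned zero divisions. Death rates
estimated from segregation data land exactly on 1 with probability zero,
so this is a representational boundary, not a practical limitation.

**Desk-scale runs.** A `scale` setting divides all sizes by a factor and
multiplies μ by the same factor, preserving the expected event count
m = μ·ΣB_k. This is an approximation valid when per-interval B ≫ 1. The
packaged studies run at final size 1e5 and μ = 1e-5 — keeping m of order
one as in typical assays — rather than the experimental 1e9 and 1e-9,
purely as a simulation-size choice; the scale-invariance of the
distribution shape at fixed m is itself under test.

## Classic (no-death) estimation

`mss_pmf` implements the standard recursion; `mle_m` maximises the
resulting likelihood over m ≥ 0 (bounded scalar optimisation in log m) and
reports a profile-likelihood interval at a 1.92 log-likelihood drop
(asymptotic 95%). Counts above kmax (default: largest observed count,
capped at 1500) are pooled into the 1 − Σp tail mass — this is the jackpot
handling, and it also bounds the O(kmax²) recursion cost; jackpot cultures
then inform the fit only through "count exceeded kmax", which is exactly
the robustness one wants from a heavy-tailed distribution. The classic
rate is μ̂ = m̂/N_final (initial size neglected as ≪ N_final). Partial
plating is refused by design: plating corrections for the classic
likelihood are approximate, while the simulation-based estimator handles
thinning exactly, so partial-plating data are routed there.

## Corrected (simulation-matching) estimation

For each candidate rate on a log-spaced grid, `sims_per_rate` cultures are
simulated under the measured profile (including plating thinning) and the
observed counts are scored by a smoothed empirical log-likelihood:
counts 0..kcap get individual bins and everything above kcap one tail bin,
with kcap set to the 95th percentile of the *observed* counts. Fixing the
bin structure across the grid keeps pooled likelihoods comparable between
candidate rates (a per-rate threshold would let implausibly low rates hide
all observed counts in one tail bin); the single tail bin prevents an
observed jackpot from dominating. Additive smoothing (pseudocount 0.5)
keeps the likelihood finite on bins unvisited by simulation.

With a uniform prior on log rate, the reported estimate — the grid argmax —
is the MAP and coincides with the grid-restricted maximum likelihood. A
local quadratic in log₁₀-rate fitted to the seven profile points around the
argmax refines the estimate below the grid resolution and averages out
Monte-Carlo noise; the default grid is 41 points spanning ±2 orders of
magnitude around a pilot estimate (classic MLE, naively rescaled for
plating and divided by the profile's division count). The confidence
interval collects grid points within 1.92 log-likelihood units of the
maximum. An optimum on the grid boundary is flagged ("grid too narrow")
but still returned. A Wasserstein-distance variant (argmin of the distance
between simulated and observed counts, bootstrap percentile interval) is
available as an alternative; the likelihood variant is the default because
it uses the full distribution and yields a natural interval. `m_hat`
reports rate × ΣB_k, the implied expected number of mutational events.

Identifiability: death rates and mutation rate are not jointly identifiable
from mutant counts alone; d must come from the segregation data, and only μ
is inferred.

## Evolvability

Evolvability is quantified as the absolute number of mutants in the final
population (observed counts divided by the plating fraction, so cultures
plated at different fractions are comparable). The no-death counterfactual
simulates cultures growing from the same inoculum to the same final size
at d = 0 with the same (corrected) rate, as a single growth phase: under
zero death the mutant-count law depends on the trajectory only through the
initial and final size, and declining trajectories have no size-matched
zero-death counterpart, so the single-phase construction is both exact
where a multi-phase d = 0 profile exists and well-defined where it does
not. The turnover contribution is the ratio of mean supplies with a
bootstrap percentile interval; mean comparisons offer both Welch's t test
(default, matching common practice for replicate means) and the
Mann–Whitney U test (robust to the jackpot tail).

## Synthetic fixtures

`make_fixture` generates, per regime, a ground-truth profile on the 0/3/6/
24 h sampling grid, the deterministic segregation recursion with Poisson
plate-count noise, and a mutant-count dataset simulated at a stated true
rate (default 1e-5 at desk scale, 24 cultures). The regimes emulate
qualitatively distinct stress dynamics: persistent death with reduced
final size (norfloxacin-like), death only near stationary phase with
unaffected final size (H₂O₂-like), early net decline (d > 1) followed by
recovery under continued death (kanamycin-like), and an untreated control.
Trajectories were chosen once so that expected mutational events per
culture are of order one in every regime. Fixtures default to full plating
so that both estimators can run on the same dataset (the classic estimator
refuses partial plating); the plating fraction is an explicit parameter.

What the fixtures do **not** emulate: day-to-day batch effects, plating
efficiency drift, differential mutant fitness, phenotypic lag,
filamentation/ploidy effects, or death-rate heterogeneity within an
interval. Passing the recovery studies therefore demonstrates correctness
of the inference machinery under the stated model, not robustness to every
artefact of real plate data.

## Numerical choices and degenerate inputs

- Likelihood floors at 1e-300 before logs; probabilities clamped at ≥ 0.
- All-zero counts: classic m̂ = 0 with CI [0, 1.92/C]; the corrected
  estimator returns the lowest grid rate with a boundary flag.
- Tie-break at d = 1 exactly: zero divisions (see above).
- Division counts, durations and birth–death parameters are computed in
  double precision; the round-trip segregation inversion is exact to
  ~1e-16 without noise.
- Seeds: every stochastic entry point takes an explicit seed or Generator;
  studies derive per-assay seeds from one master seed, so all packaged
  results are bit-reproducible.

## Known limitations

- The corrected estimator's resolution is set by the grid and refinement
  (a few percent by default); tighten the grid for finer work.
- Very low expected event counts (m ≲ 0.1) leave most cultures at zero
  mutants and all estimators weakly informed; widen the assay instead.
- The plasmid-segregation method needs net growth of untreated cultures
  and a measurable F decline; it cannot anchor generations in stationary
  populations.
- Wall-clock times in profiles are carried through for reporting but do
  not influence inference, by construction of the per-division model.
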