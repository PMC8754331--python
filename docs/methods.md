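# Methods

## Model

Each of `N` neurons follows the rate equation
`tau dr_i/dt = -r_i + phi(h_i)` with the sigmoidal f-I curve
`phi(h) = r_max / (1 + exp(-b(h - h0)))`.  Binary patterns
`xi^mu ∈ {0,1}^N` of sparsity `gamma` define Hopfield–Tsodyks couplings
`w_ij = A/(N gamma(1-gamma)) Σ_mu (xi_i^mu - gamma)(xi_j^mu - gamma)`;
with these mean-subtracted factors independent patterns give `<w_ij> = 0`
and `<w_ij^2> = A^2 P / N^2`.  The full input optionally includes a
neuron-specific adaptation current `theta_i`
(`tau_theta dtheta/dt = -theta + theta0 + D_theta r`), a global inhibitory
feedback `-J0(t)/(gamma N) Σ_j r_j` whose strength can be modulated
sinusoidally between `J_min` and `J_max` with period `T_J0`, and external
cues.

All computation is done in dimensionless units: time in `1/r_max`, currents
in `A r_max`, rates in `r_max`.  The dynamics then depends on the pattern
statistics only through `(gamma, C, alpha)` and on the neuron only through
`b_hat = b A r_max` and `h0_hat = h0/(A r_max)`.  Association between two
concepts is a shared-neuron fraction `c = P(xi^nu=1 | xi^mu=1)`, linked to
the Pearson correlation of the binary patterns by `c = C(1-gamma) + gamma`;
`c = gamma` is chance.

## Mean-field reduction

For `n ≤ 4` correlated patterns the neurons split into `2^n`
joint-selectivity populations with probabilities `P_x` (closed form in
`(gamma, C)` for pairs; the permutation-invariant copy/flip parent form for
triples/quadruples).  The population input is

```
h_x = Σ_nu (x^nu - gamma) m^nu + I_x - theta_x - (J0/gamma)<r> + sqrt(alpha R) z,
```

and `tau dm^mu/dt = -m^mu + Σ_x P_x (x^mu-gamma)/(gamma(1-gamma)) <phi(h_x)>_z`.
At `alpha = 0` (the regime of most results; the load dependence is weak)
the Gaussian integrals collapse and the equations are exact.  Numerical
choices:

- Gaussian integrals by Gauss–Hermite quadrature, 101 nodes by default
  (201 recommended near the Heaviside regime); for `b_hat > 1000` the
  solver switches to the erfc closed forms of the step-function limit.
- With global inhibition the mean rate `u = <r>` enters every input as
  `-(J0/gamma) u`; the map `u → Σ P_x <phi>` is strictly decreasing, so the
  inner self-consistency is solved with `brentq` to 1e-13.
- The background noise `R = p/(1-q)^2` (with `q = <phi'>`, `p = <phi^2>`)
  is solved by damped fixed-point iteration (damping 0.5, tolerance 1e-11);
  the paper-style grid-acceptance scan over `R ∈ [0, 0.3]` is kept as an
  independent oracle.  An absent solution is reported as `None`, not an
  exception, so scans can skip the state.
- Excluding self-interaction adds `q alpha phi(h)/(1-q)` to the input,
  solved recursively on the population mean inputs (the first-order-in-`z`
  approximation); in the step-function limit it reduces to the constant
  `alpha/2`.
- Background patterns correlated in disjoint groups of `p` rescale `R`
  through the coupling matrix `M = (1-q)I - qC(J - I)`; its inverse is the
  Sherman–Morrison closed form and the effective value is
  `R = p_pop · tr(K M⁻¹ K M⁻¹)/p` with `K` the group correlation matrix.
  The printed pair form in the source material is garbled; this expression
  was re-derived from the linear system and is tested against dense
  inversion.  Letting *all* patterns share correlation makes the noise
  variance scale as `P²/N`, which diverges at fixed load — that case is
  rejected with an explanatory error.

Fixed points are found by multi-start `scipy.optimize.root` (hybr, xtol
1e-12) from a grid of seeds plus targeted retrieval-state seeds,
deduplicated at 5e-4 and verified by re-evaluating the residual (< 1e-8).
Stability comes from the Jacobian — analytic at zero load (including the
implicit derivative of the inhibition feedback), central finite differences
otherwise — with eigenvalue threshold 1e-6 for the marginal class.  In the
Heaviside zero-load mode the transfer is piecewise constant, so all
self-consistent population-activation configurations are enumerated exactly
(2^(2^n) candidates) and classified stable (plateaus) or marginal (on a
threshold).

## Bifurcation extraction

`c_max` is the largest `c` at which a stable single-retrieval state
(`m1 > 0.55`, `m1 - m2 > 0.08`) exists; its disappearance is the
saddle-node where the retrieval state merges with its companion saddle.
The extractor continues the state in `C` with targeted seeding and bisects
on existence, coarse step 1e-3 and local refinement 1e-4 (reported value
carries ± one refined step).  Without inhibition the search is bracketed by
the analytic bound `c_max ≤ gamma + (1-gamma) h0_hat` (equivalently
`C_max ≤ h0_hat`).  `c_min` (with global inhibition) bisects on the
appearance of a stable symmetric state `m1 = m2 > 0.5`; the chain bounds
(`c_min'`, `c_max'`) use the same machinery at `J0 = J_max` (transition
state `m1 = m2 > 0`, distinct from rest) and `J0 = J_min` (both single
retrievals present), with adaptation frozen at `theta = 0`.

In the analytic limit (`b → ∞`, `alpha = 0`, `gamma → 0`) only three
populations survive and the retrieval state's second overlap is exactly
`m2 = C` for `C < h0_hat`, so the extracted `C_max` equals `h0_hat`; this
closed path is implemented separately and used as an exactness check.

At the reference parameters (`h0_hat = 0.25`, `b_hat = 100`,
`gamma = 0.2 %`) the extraction gives `c_max = 20.0 %`.  A scalar reduction
of the retrieval state (`m2 = C + (1-C) phi(m2)` at `m1 = 1`) places the
tangency at `C ≈ 0.196–0.199` and confirms the value; the supplementary
phase-plane material of the source study treats `C = 0.2` as supercritical
at these parameters, consistent with this number.

## Pattern constructions

Four algorithms build a subgroup of `K` engrams with pairwise sharing `c`:

- **Parent copy/flip**: each pattern equals a parent bit (sparsity
  `lambda`) with probability `epsilon`; `(lambda, epsilon)` solve a cubic
  in `epsilon` with `lambda = (gamma+eps-1)/(2 eps-1)`; of the admissible
  roots the `epsilon < 1/2` branch is used, the others are exposed via
  `return_all`.  This is also the generative model behind the 3- and
  4-pattern joint probabilities.
- **Hierarchical generative**: parent of sparsity `lambda = gamma/c`
  (requires `c ≥ gamma`); children copy parent ones with probability `c`
  and never activate elsewhere.  Response counts follow
  `P_K(k) = binom(K,k) lambda c^k (1-c)^(K-k) + (1-lambda) delta_k0`.
- **Indicator neurons**: indicators (sparsity `lambda_ind`) join each
  pattern with probability `1-epsilon`, all others with probability
  `Omega`; the sharing condition is
  `c gamma = lambda_ind (1-eps)^2 + (1-lambda_ind) Omega^2` and
  `epsilon = Omega` is imposed by 1-D fixed-point iteration
  (tolerance 1e-10).  Response counts are the two-component binomial
  mixture with mean `K gamma`.
- **Iterative overlap-generating** (non-hierarchical): exact integer
  counts — `round(gamma N)` active per pattern; each new pattern compares
  against earlier ones in descending index order, counts pre-existing
  intersections, tops the pair up to `round(gamma c N)` from that pattern,
  and fills from never-used neurons.  Pairs are exact for `K = 2` and for
  each pattern's last-compared partner; other pairs can pick up accidental
  excess (never a deficit) because a top-up neuron may also belong to an
  already-finalized partner — the excess the algorithm is known for at
  large `K`, where late patterns over-correlate.

RNG: one root seed per ensemble, fanned out into per-pattern substreams, so
extending an ensemble never perturbs earlier patterns.  Patterns are stored
as index sets (`gamma N ≈ 200` of `N = 1e5`).

A fifth construction (`generate_iterative_groups`) supports *overlapping
subgroups* (e.g. one person associated with two contexts).  It additionally
draws top-ups preferentially from neurons exclusive to the compared
pattern, keeping the pairwise shared sets disjoint (the Venn-diagram
structure): without this, chance triple intersections shrink the distinct
shared drive and break the context-disentangling experiment in ~1/3 of
seeds.

## Simulator

Full connectivity uses the factored pattern-space coupling
(`h_i = Σ_mu (xi_i^mu - gamma) m^mu`), exactly equivalent to the explicit
matrix without the `N²` memory; excluding self-interaction subtracts the
per-neuron diagonal term.  Dilution (`d < 1`) requires the explicit
Bernoulli-masked matrix with `1/d` compensation and is limited to a few
thousand neurons by memory (a documented guard).  Integration is forward
Euler with default `dt = tau/10`; `dt > tau/5` warns and divergence aborts
with a diagnostic.  "Initialized to retrieve" a memory means rates
`r_max` on its members and 0 elsewhere.  Heterogeneous f-I curves draw
per-neuron `(r_min)_i, (r_max)_i` from Gaussians (redraw on
`r_max ≤ r_min` or `r_min < 0`); rates are affinely rescaled before
entering the recurrence and the overlap readout, so vanishing spread
reproduces the homogeneous model exactly.

### Adaptation strength

The adaptation strength `D_theta` has no published value.  The default
`D_theta_hat = 0.1` follows from the input budget of the chain regime at
`c = 20 %`: the transition state at peak inhibition leaves an input margin
of about `0.8 c J_max/(...) ≈ 0.16` for the shared neurons, which the
accumulated adaptation of the bridging population must not exhaust, while
any nonzero fatigue difference suffices to bias the next transition.  It is
an exposed parameter; `D_theta_hat = 0.3` suppresses sustained alternation.

### Mean-field vs network comparisons

At `gamma N ≈ 20` neurons per engram (N = 1e4), Bernoulli constructions
have ±22 % sparsity fluctuations that dominate the overlap (values above 1,
spurious ignition).  Protocol-level comparisons with the theory therefore
use the exact-count iterative construction, after which agreement is at
machine precision for the two-pattern protocol.

### Chain dynamics (quasi-static theory)

With `tau ≪ T_J0 < tau_theta` the overlaps are relaxed to quasi-equilibrium
at each outer step (Euler relaxation to `|dm| < 1e-7`), the four population
rates being solved self-consistently through the inhibition loop; the
population adaptations `theta_x` then advance by one Euler step.  The
default regime (`tau_theta_hat = 45`, `T_J0_hat = 25`,
`J0 ∈ [0.7, 1.2]`, `h0_hat = 0`) sustains alternation between correlated
patterns at `c = 20 %` and shows none at chance overlap.

### Context-disentangling experiment

Five concepts (persons P0, P1, P2; contexts C1, C2) are stored with
subgroups {P0, P1, C1} and {P0, P2, C2} at within-group `C = 0.1`
(`N = 2·10^4`, static model).  With disjoint pairwise overlaps the recall
cascade of the cued person takes ~2 tau once person and context are both
active, while the weak ambiguous cue alone drives a much slower upward
drift of the person overlaps (their intermediate-rate shared neurons
ratchet over ~15 tau).  The protocol therefore places the context window at
`t = 9–13.8` and reads out at `t = 16`: discrimination is structural
(which overlaps exist) plus temporal (cascade vs drift).  This timing is a
design choice of the preset; a longer protocol at these parameters would
eventually ignite the weakly-cued persons regardless of context.

## Virtual experiments

Synthetic session structures stand in for the human-MTL recording design:
~100 sessions, Poisson responsive-neuron counts (mean 40.7, totalling
~4000), Poisson cluster counts (mean 8) with sizes drawn from
{1: 0.55, 2: 0.25, 4: 0.15, 16: 0.05}.  These defaults emulate the *scale*
of the experiment; the true cluster-size distribution derives from
association-score clustering of the actual stimuli and is not reproducible
here, so conclusions drawn from the synthetic sessions are qualitative
(orderings, shapes), not fits.  Per session the chosen algorithm builds one
subgroup per cluster in a shared `N = 1e5` pool (cross-subgroup sharing by
chance), responsive neurons (≥ 1 membership) are sampled without
replacement to the session's count, and counts are histogrammed over
`k = 1..max K`; 40 repetitions give mean ± SD.  The closed-form mixture
assumes strictly disjoint subgroups:
`Psi_s(k) = Σ_j P_{K_j}(k) / Σ_j (1 - P_{K_j}(0))` and
`Psi_final = Σ_s N_s Psi_s / Σ_s N_s`; the small theory-vs-sampling
mismatch measures the violated disjointness.

## What the tests do and do not show

The suite verifies the algebraic identities exactly, the generators against
4-standard-error statistical bands (pooling over seeds where a common hub
set correlates all pairs of one ensemble), the mean-field equations against
independently hand-coded forms, the extraction machinery against analytic
limits and bounds, and the network against the theory at desk scale
(`N = 1e4–1e5`, reduced bisection resolution).  Real recordings enter
nowhere; agreement with the synthetic sessions shows the algorithms'
*relative* behavior (only the non-hierarchical construction produces
substantial multi-responsive mass), not a fit to data.

## Known limitations

- Closed-form mean field covers up to 4 mutually correlated patterns;
  arbitrary correlation matrices are out of scope.
- The combination `alpha > 0` with time-varying inhibition iterates two
  nested self-consistencies and is slower and less hardened than either
  alone.
- Diluted simulation is memory-limited to small `N`; very sparse
  connectivity at large `N` is not optimized.
- Negative pattern correlations are not representable by any of the
  constructions.
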