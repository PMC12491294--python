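# Methods

## Model

`phagedyn` studies a four-species compartment model of a bacteriophage
attack on a bacterial colony. The state is X = (S, I, P, R): susceptible
bacteria, infected bacteria, free phage load, and phage-resistant bacteria
(all concentrations):

    dS/dt = -k0(P,R) S + mu S (1 - S/K)
    dI/dt =  k0(P,R) S - k1 I
    dP/dt =  q I - k2 P
    dR/dt =  alpha I (1 - R/Rm)

with the defense-modified contact rate

    k0(P,R) = beta0 P / (1 + gamma R).

The S/I/P core is the familiar TIV (target cell / infected cell / virion)
structure; the R equation is a minimal description of an adaptive,
CRISPR-like defense: infection drives the growth of a resistant phenotype
(rate `alpha`, saturating at `Rm`), and resistant cells lower the effective
contact rate between phages and susceptibles (effectivity `gamma`). Both
defense knobs can be switched off independently (`alpha = 0`, `gamma = 0`).
Logistic growth of susceptibles (`mu`, capacity `K`) is optional; it has no
effect on the quantities that organize the initial outbreak (see below).

Parameters and their units: `beta0` [1/(conc·day)], `gamma` [1/conc],
`alpha`, `q`, `k1`, `k2`, `mu` [1/day], `Rm`, `K` [conc]. Required:
`k1, k2, q, beta0 > 0`, `alpha, gamma, mu >= 0`, `Rm > 0`, and `K > 0`
whenever `mu > 0`.

### Dimensionless form

`to_scaled` maps the model to dimensionless variables s = S/Sst0,
i = I/Sst0, p = k1 P/(q Sst0), r = R/Rm. The key point of the p-scaling is
that phage load is measured in bacteria-equivalent units: the scaled
production term `k1 i` matches the infected decay `-k1 i`, so one infected
bacterium converts to one phage unit. The scaled system is the *same* model
family with parameters beta0' = beta0 Sst0 q/k1, gamma' = gamma Rm,
alpha' = alpha Sst0/Rm, Rm' = 1, q' = k1, K' = K/Sst0 — so a single
right-hand side serves both forms, and scale-then-simulate equals
simulate-then-scale exactly (the transform is diagonal-linear and commutes
with the Euler step; tested to 1e-12).

## Fixed points and spectrum

Before the attack the colony sits in a phage-free fixed point
Xst0 = (Sst0, 0, 0, Rst0) with Rst0 in [0, Rm]; with growth switched on,
stationarity additionally forces Sst0 = K. An endemic state exists (for
mu > 0) iff even a saturated resistant population cannot stabilize the
phage-free point, k1 k2 < q beta0 K/(1 + gamma Rm); its properties are out
of scope here.

The Jacobian at Xst0 has a closed (I,P) block [[-k1, F0], [q, -k2]] with
F0 = beta0 fst0 Sst0 and fst0 = 1/(1 + gamma Rst0), giving eigenvalues

    lambda_1 = -mu,  lambda_4 = 0,
    lambda_{2,3} = -(k1+k2)/2 ± sqrt((k1+k2)^2/4 - k1 k2 + q F0).

The discriminant equals (k1-k2)^2/4 + q F0 > 0, so the pair is always real;
lambda_3 < 0 for every valid parameter set, while lambda_2 crosses zero
exactly at the epidemic threshold: with the next-generation reproduction
number R0 = q F0/(k1 k2), sign(lambda_2) = sign(R0 - 1). Case I
(lambda_2 < 0, R0 < 1) means no outbreak; case II (lambda_2 > 0, R0 > 1)
means the fixed point is unstable and v2, the eigenvector of lambda_2, is
the **order parameter**: the multi-species direction along which the
outbreak self-organizes.

Eigenvectors are evaluated from the closed forms (v1 = e_S, v4 = e_R
exactly; for j = 2,3 the solution of J v = lambda v, normalized to unit
length). Using the analytic null-space vectors keeps the mu = 0 case — a
double zero eigenvalue — well defined where a numeric eigensolver would
return an arbitrary basis. The dual (bi-orthogonal) vectors w_j with
w_i·v_k = delta_ik are computed by inverting the eigenvector matrix; the
known closed forms of w2, w3 (proportional to the (I,P) components of the
opposite eigenvector over B = v2_I v3_P - v2_P v3_I) and w4 serve as
cross-checks in the test suite, not as the implementation, because the
inversion contract is unambiguous.

**Sign convention.** Unit normalization fixes eigenvector length only; the
sign is fixed so the P-component is >= 0 (tie-break: I-component >= 0).
All amplitude signs downstream inherit this choice; with it, the order
parameter has S-component < 0 and I, P-components > 0 in the outbreak
regime — susceptibles fall while infection and phage load rise together.

**Growth-term invariance.** lambda_2 and the (I,P,R)-orientation of v2
contain no mu, so the initial outbreak organization is identical with and
without bacterial growth at matched Sst0 = K (tested to 1e-12).

## Amplitude equations

Writing X = Xst0 + sum_j A_j v_j and projecting with the dual basis gives
the exact closed system dA_j/dt = lambda_j A_j + w_j·G(u), where
u = X - Xst0 = (delta, I, P, omega) and

    G = (-G_I - (mu/K) delta^2,  G_I,  0,  G_R),
    G_I = beta0 P [(Sst0+delta)/(1+gamma(Rst0+omega)) - Sst0/(1+gamma Rst0)],
    G_R = -alpha I omega / Rm.

The identity rhs(Xst0 + u) = J u + G(u) holds exactly (no expansion) and is
the master consistency oracle of the package, tested componentwise to
1e-12 over random displacements. Because the coordinate change is linear,
a forward-Euler step in amplitude space maps algebraically onto a
forward-Euler step in state space; the two integrations agree to rounding
(~1e-14 over a 7-day run), which the tests assert at the much looser
Euler-order tolerance 10·dt.

### Reduced descriptions

- **Order-parameter approximation.** Early in a case-II outbreak,
  Delta X(t) ≈ v2 A2(0) (exp(lambda2 t) - 1): the whole network moves along
  one direction, and the rank-1 description includes the defense reaction
  through v2's R-component. The constant offset of the full form is kept as
  an explicit vector built from the initial amplitudes along the neutral
  directions (A4 always; A1 only when mu = 0), avoiding any symbol clash
  with the carrying capacity.
- **Stopping mechanisms.** Expanding N2 to second order splits the braking
  of exponential growth into a passive term ∝ -P·delta (depletion of
  susceptibles) and an active term ∝ gamma Sst0 fst0 P·omega (accumulation
  of resistant mutants), sharing the prefactor c = w2_I beta0 fst0 (the
  1/B normalization is carried inside w2_I). With the sign convention above
  c > 0 in the outbreak regime and both braking terms are >= 0 whenever
  delta <= 0, omega >= 0, P >= 0. The neglected remainder is O(eps^3) under
  eps-scaling of u, verified numerically over eps = 1e-2 .. 1e-4.
- **Linear predictors.** On the order-parameter line every species is a
  linear function of every other: X_i ≈ a_ij + r_ij X_j with
  r_ij = v2_i/v2_j and a_ij = Xst0_i - r_ij Xst0_j (so the I-from-P
  intercept is exactly zero). Pairs with v2_j = 0 have no defined slope and
  are reported as NaN.
- **Double-exponential approximation.** v1 and v4 have no (I,P) components,
  so the infected/phage pair is carried by (A2, A3) alone — an exact 2D
  reduction at all times. Dropping the nonlinear coupling yields
  (I,P)(t) ≈ v2' A2(0) e^{lambda2 t} + v3' A3(0) e^{lambda3 t}, which is
  exact at t = 0 and describes both the fast transient toward the order
  parameter and the subsequent growth along it.

## Scenarios and numerics

The packaged scenarios are the two canonical outbreak experiments in the
dimensionless model, differing only in the defense:

| | beta0' | gamma' | alpha' | k1 | k2 | s0 | r0 | p(0) | dt | horizon |
|---|---|---|---|---|---|---|---|---|---|---|
| passive | 5 | 0 | 0 | 0.2 | 1 | 1 | 0.01 | 0.001 | 0.001 d | 7 d |
| active  | 5 | 5 | 1 | 0.2 | 1 | 1 | 0.01 | 0.001 | 0.001 d | 7 d |

(mu = 0 in both; q = k1 in the scaled family.) These are deterministic
configurations, not stochastic data: the pipeline contains no randomness,
and re-running a scenario file reproduces the CSV byte-identically. What
passing tests show is therefore the internal consistency of the analysis
(spectrum, amplitudes, approximations) under the model's own assumptions —
they say nothing about demographic noise, burst-size distributions, spatial
structure, or measurement error in real phage–bacteria systems, none of
which the model represents.

Numerical choices:

- **Integrator.** Forward Euler, as the simplest scheme that keeps the
  amplitude/state conjugacy exact at the discrete level. Default
  dt = 0.001 day: halving dt moves the 7-day endpoint by far less than 1%
  on both scenarios, and the drift halves again with dt (order-1
  convergence, tested). dt is a scenario field, not a constant.
- **No clamping.** States are validated, never silently corrected; a
  negative excursion or non-finite value from a too-large dt raises a
  diagnostic (`IntegrationError` with the step index) instead of being
  repaired.
- **Degeneracy guards.** Eigenvector construction refuses eigenvalues
  within 1e-12 (relative to the spectral gap) of 0, -mu, or -k1, and the
  dual-basis inversion refuses condition numbers above 1e10; the exact
  threshold R0 = 1 surfaces as an explicit degeneracy/threshold error
  rather than a garbage basis.
- **Predictor regression window.** Checks that recover r_ij by least
  squares from a simulated trajectory use t in [2, 4] days. The lower edge
  waits out the fast transient along v3 (by t = 2, e^{2 lambda3} ≈ 4% of
  the transverse component remains — early on the phase curve is *not* on
  the order-parameter line: the phage load initially dips, because
  dp/dt(0) = -k2 p(0) < 0, while infection builds); the upper edge stays
  well before nonlinear saturation. Within that window the slopes match the
  v2 ratios to a few percent.
- **Alignment metric.** The "phase curves converge to the order parameter"
  statement is quantified as the angle between the displacement X(t) - Xst0
  and span(v2) (sign-insensitive); both scenarios hold < 5 degrees for a
  sustained window of more than a day. The departure from the
  double-exponential track is the relative Euclidean (I,P) error, with the
  10% first-crossing time as the summary scalar; the active defense crosses
  strictly earlier (≈ day 4.1) than the passive scenario (which stays under
  10% through the whole week), reflecting that resistant mutants weaken the
  linear order-parameter link sooner.
- **Serialization.** Floats are written with 17 significant digits and read
  back with round-trip parsing, so CSV output is lossless.

## Limitations

- Only the phage-free fixed point is analyzed; endemic-state structure and
  stability are out of scope.
- The defense enters solely through the contact rate; alternative
  mechanisms (abortive infection, restriction enzymes, …) are not modeled.
- The reduced descriptions are early-time asymptotics; none of them
  captures the saturation and eventual resolution of the outbreak.
- The integrator is deliberately first-order; users needing tight long-time
  accuracy should shrink dt rather than expect adaptive stepping.
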