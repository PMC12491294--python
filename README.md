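# phagedyn

Order-parameter analysis of bacteriophage infection outbreaks in a
bacterial colony with an adaptive (CRISPR-like) defense.

`phagedyn` is for modelers of phage–bacteria dynamics who want more than a
state-space integration: it computes the *direction* along which an
outbreak self-organizes and the reduced descriptions that direction
induces, together with quantitative measures of how long those reductions
stay valid.

## The model

Four interacting species — susceptible bacteria S, infected bacteria I,
phage load P, resistant mutants R:

    dS/dt = -k0(P,R) S + mu S (1 - S/K)        k0(P,R) = beta0 P / (1 + gamma R)
    dI/dt =  k0(P,R) S - k1 I
    dP/dt =  q I - k2 P
    dR/dt =  alpha I (1 - R/Rm)

Infection drives the growth of a resistant phenotype (rate alpha), and
resistant cells shield susceptibles by lowering the contact rate
(effectivity gamma). Before an attack the colony sits in a phage-free
fixed point Xst0 = (Sst0, 0, 0, Rst0); a phage inoculum P(0) > 0 at t = 0
starts the outbreak.

The linearization at Xst0 has closed-form eigenvalues: lambda_1 = -mu,
lambda_4 = 0 and

    lambda_{2,3} = -(k1+k2)/2 ± sqrt((k1+k2)^2/4 - k1 k2 + q F0),

with F0 = beta0 Sst0/(1 + gamma Rst0). With the basic reproduction number
R0 = q F0/(k1 k2) (next-generation method), sign(lambda_2) = sign(R0 - 1):
for R0 > 1 the fixed point is unstable and the eigenvector v2 of lambda_2
is the **order parameter** — the multi-species direction that captures the
joint fall of susceptibles, rise of infection and phage load, and the
defense reaction. Projecting onto the bi-orthogonal dual basis w_j turns
the model into exact amplitude equations dA_j/dt = lambda_j A_j + N_j(A),
from which the package derives the rank-1 order-parameter approximation,
the passive/active stopping-term decomposition, linear predictor slopes
r_ij = v2_i/v2_j between species, and the double-exponential approximation
of (I, P).

## Worked example

Two scenarios of the dimensionless model ship with the package: `passive`
(defense off: alpha' = gamma' = 0) and `active` (alpha' = 1, gamma' = 5),
both with beta0' = 5/day, k1 = 0.2/day, k2 = 1/day, a colony at s0 = 1
with r0 = 0.01, and an inoculum p(0) = 0.001 integrated over one week.

```python
import phagedyn as pdn

res = pdn.run_scenario(pdn.passive_scenario())
sp = res.spectral
print("eigenvalues:", [f"{v:.6f}" for v in sp.lambdas])
print("R0:", sp.R0, " case:", sp.case_label)
print("order parameter v2:", [f"{v:.6f}" for v in sp.v2])
print("I-from-P slope:", f"{pdn.predictor_slopes(sp)[1, 2]:.6f}")
print("aligned window [d]:", round(res.metrics["longest_aligned_window"], 3))
print("10% departure time [d]:", res.metrics["first_deviation_time"])
```

prints

    eigenvalues: ['-0.000000', '0.477033', '-1.677033', '0.000000']
    R0: 5.0  case: II
    order parameter v2: ['-0.814989', '0.574236', '0.077755', '0.000000']
    I-from-P slope: 7.385165
    aligned window [d]: 5.303
    10% departure time [d]: 7.0

Reading: R0 = 5 > 1, so the inoculum triggers an outbreak (case II) growing
at lambda_2 = 0.477/day. The outbreak organizes along v2 — susceptibles
fall while infected bacteria and phage load rise in the fixed ratio
I ≈ 7.39 P — and the simulated phase curve stays within 5° of that
direction for a sustained 5.3 days. The two-exponential (I, P)
approximation never departs by more than 10% within the week. Running the
`active` scenario instead gives R0 = 4.762, a slightly slower outbreak
(lambda_2 = 0.455/day), and a 10% departure already at day 4.14: the
accumulating resistant mutants brake the growth and weaken the linear
order-parameter links earlier.

The same runs from the shell:

    phagedyn fixtures                               # list packaged scenarios
    phagedyn analyze  --scenario passive            # spectral report (JSON)
    phagedyn simulate --scenario active --out out/  # trajectory CSV + reports

`simulate` writes `trajectory.csv` (columns t, s, i, p, r, A1..A4, the
order-parameter track op_*, and the double-exponential track dexp_*),
`spectral.json`, `metrics.json` and a run manifest. Custom scenarios are
YAML files; the schema is documented in `phagedyn/io.py` and validated
strictly (unknown keys are errors). Exit codes: 0 success, 2 validation
error, 3 numerical failure.

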