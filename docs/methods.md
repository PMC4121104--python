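# Methods

## Model

The plant is a five-state negative-feedback oscillator for the core
circadian circuit: mRNA `x1`, cytosolic protein `x2`, its two successive
phosphoforms `x3`, `x4`, and the nuclear repressor `x5` (all in nM).  All
conversion and degradation steps are Michaelis–Menten saturating terms
`v·x/(K+x)`; transcription is repressed by the nuclear protein through the
decreasing Hill function `vs·KIⁿ/(KIⁿ + x5ⁿ)`; the environmental input
`u(t)` (nM/h) enters the mRNA balance additively.  The default parameter
set (see `ModelParameters`) yields a stable limit cycle whose period the
package *measures* as ≈ 22.3 h — near-circadian, and reproduced
identically (±0.5 h tested) from random initial conditions.

Supported inputs: zero, `ε·sin(t)` (argument in hours as written, i.e.
period 2π h — deliberately *not* 24 h), a step (0 for `t ≤ onset`, `level`
after), and a rectangular pulse (`level` on the open window
`onset < t < offset`).  Discontinuous inputs are handled by splitting the
integration at the breakpoints so the solver never steps across a jump.

### Positivity

With `u(t) ≥ 0` the closed positive orthant is forward invariant (every
derivative is nonnegative on its zero face), so the integrator enforces it:
sampled values below −10⁻⁷ nM raise, values in (−10⁻⁷, 0) are round-off
and are clamped to 0.  A negative-going input breaks the invariance *in the
model itself*, not in the solver: at the nuclear-protein peak (x5 ≈ 6.2 nM)
Hill production is only ≈ 0.005 nM/h, so `u = 0.1·sin(t)` drags the mRNA
about 0.04 nM below zero on every cycle trough.  Those runs are therefore
integrated exactly as written (the Michaelis poles at −K are far away) and
the small negative excursions are reported rather than masked.  Bounds:
from a unit initial state all states stay below 10 nM unforced (below
20 nM under the shipped forcings); large random initial transients can
overshoot briefly.

## Observers

The observer is a copy of the model driven by output injection,
`dz/dt = f(z,u) + K(y − Cz)`.  Two configurations are first-class: a single
sensor on the mRNA (gain `k`, output scaling `c`, injection `kc(x1 − z1)`
into the first equation only) and a dual sensor on mRNA + protein (gains
`α, β`, scalings `c1, c2`); `ObserverConfig` accepts any sensor subset.
Plant and observer are integrated as one 10-dimensional system with
continuous measurement — no sampling or noise, matching the idealized
setting.  The observer state is *not* confined to the positive orthant (it
is a mathematical construct); a guard raises if a Michaelis denominator
`K + z` comes within 10⁻⁶ of zero.

`convergence_time(err, tol)` is the first sampled time after which
`maxᵢ|eᵢ|` stays below `tol` (default 10⁻³ nM — the natural error scale is
nM, and "converges quickly" needs a number to be testable) through the end
of the run; a late re-crossing restarts the
clock, and "never" is `inf`.

**Measured, perhaps surprising:** the settling time is *not* monotone in
the gain.  For the free-running scenario, k = 1 settles in ≈ 40–55 h while
k = 5 and k = 10 need ≈ 60–140 h across seeds.  Injection acts only on the
measured mRNA error; overall convergence is dominated by phase-locking of
the four unmeasured states onto the plant's limit cycle, which a stiffer
x1-correction does not accelerate.  The tests therefore assert finite
settling at every gain, not an ordering.

## Lyapunov certification

For the single-sensor error dynamics, each Michaelis difference is
rewritten exactly with the mean value theorem,
`g(K,x) − g(K,z) = K/(K+ξ)²·(x − z)` for some ξ between x and z (similarly
for the Hill term, slope `n·vs·KIⁿ·ξ⁵ⁿ⁻¹/(KIⁿ + ξ5ⁿ)²`).  The derivative of
`V = ½Σeᵢ²` is then `eᵀQe` with a symmetric `Q(ξ)` whose seven mean-value
coordinates (ξ3/ξ3′ and ξ4/ξ4′ belong to different Michaelis constants
applied to the same variable and are scanned independently) live between
the plant and observer trajectories.  Only the (1,1) entry contains the
gain (as `−kc`); the (1,5) entry carries the Hill cross term with its minus
sign, and (5,5) = −k2 always.

`certify_over_box` evaluates `Q` on a regular grid over a state box
(default 9 points per ξ dimension; each entry is monotone in its own ξ, so
the grid maximum is a tight proxy) and reports the largest eigenvalue and
its location.  This is an explicit **grid certificate**, not an interval
proof.  "Negative" means below −10⁻¹²·max(1, ‖Q‖) to absorb float noise;
the eigenvalue verdict is cross-checked against Sylvester's
leading-principal-minor test.

**Honest negative result:** on the box actually visited by the limit cycle
the sufficient condition fails for *every* gain.  The trailing 2×2 block
`[[Q44, (k1+k2)/2], [·, −k2]]` needs `Q44 < −(k1+k2)²/(4k2) = −2.25`, but
for large ξ4, ξ4′ the Michaelis slopes vanish and `Q44 → −k1 = −2`.  Since
only Q11 depends on k, no gain can repair this: `minimal_certifying_gain`
returns "none found" there, while small boxes near the origin (where the
slopes are steep) certify even at k = 0.  The observers nonetheless
converge in every simulated scenario — the Lyapunov condition is
sufficient, not necessary.

## Observability

Graph route: the inference diagram has an edge `xj → xi` when variable i
appears in equation j; SCCs via networkx; a root SCC receives no
cross-component edge (self-loops ignored).  Minimal sensor sets take one
node per root SCC.  For this model the diagram is a single 5-node root
SCC, so the five singletons are proposed.  The structural dependency of
the shipped model is a declared boolean matrix; user models supply their
own matrix.

Differential route: the model is rational, so the stacked Jacobian of a
sensor output and its Lie derivatives of orders 0–4 is formed
*symbolically* (sympy) and evaluated at requested points; rank is counted
from singular values above 10⁻⁶·σmax, with an "indeterminate" flag when
any σ falls in [10⁻⁸, 10⁻⁴]·σmax.  A nested central-difference route
(`method="fd"`) is retained as an independent cross-check: it loses ~²⁄₃
of the remaining digits per differentiation level, which is why it is
trusted only at low orders and why the symbolic route is the default —
at order 4 plus the outer Jacobian the FD entries would carry ~1 %
relative error, swamping the rank threshold.  The rank is a pointwise
(local weak observability) statement; the tests sample 10 random positive
states per sensor.

## Scenarios

Four presets pair a forcing with an observer: free-running (k=5, c=1),
sinusoid ε=0.1 (k=2.5, c=2), step 0→0.1 at t=50 (k=2.5, c=2), and pulse
0.2 on 50<t<150 with the dual observer (α=2, β=3, c1=2.2, c2=1).  Horizons
are 200 h (300 h for the pulse case, to cover re-settling after t=150);
initial plant and observer states are independent uniform draws on
[0, 2.5] nM (the limit cycle's range) from recorded seeds.  Reports carry
the plant period, settling time at 10⁻³ nM and the maximum error over the
final 20 % of the horizon, and are exactly recomputable from the written
CSV (`t,x1..x5,z1..z5,e1..e5`, 17-significant-digit round-trip).

## Numerics

* Integrator: LSODA (stiff-capable, adaptive), rtol 10⁻⁸, atol 10⁻¹⁰ —
  the Kd = 0.1 nM degradation term is sharp.  Output on a uniform 0.05 h
  grid from the solver's own interpolation, piecewise across input
  breakpoints.
* Period estimation: peak detection (scipy `find_peaks`) on the chosen
  variable after a 48 h transient cut; mean inter-peak spacing; fewer than
  3 maxima raises "no oscillation detected".
* `minimal_certifying_gain`: bisection on the gain, sound because the
  worst grid eigenvalue is non-increasing in k (only Q11 depends on it);
  an obstruction in the k-free trailing block short-circuits to "none".
* Mean-value points in tests are located by sign-change scan plus Brent
  refinement — the Hill slope is unimodal, so a plain two-endpoint bracket
  can fail.

## What the synthetic world does and does not establish

All data are generated by the model itself; there is no measurement noise,
no sampling, no parameter misspecification and no stochasticity
(molecular-noise formulations of this clock exist but are out of scope).
A green observer test therefore establishes correctness of the
deterministic coupled integration and convergence *for this model class*,
not robustness of the observer to real experimental conditions.  The
graphical sufficiency claim ("one sensor per root SCC suffices") is tested
for this network only, not asserted in general.
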