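# Methods

This note records the models implemented in `emgforce`, their
assumptions, the parameter defaults and why they were chosen, the
numerical schemes, and the design decisions taken where the literature
leaves the choice open. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Scope and assumptions

All modeling is **isometric at the joint**: the whole muscle–tendon
length is fixed at $L_{c0}\cos\varphi + L_{t0}$, so contractile-element
(CE) shortening stretches the series tendon. Only concentric CE
behavior is modeled; the parallel elastic element is omitted (its
length does not change isometrically). Forces are assembled into ankle
plantar-flexion torque through fixed moment arms and compared on an
MVC-normalized scale, which removes subject-strength effects and most
sensitivity to the absolute values of $F_m$.

## EMG conditioning

Steps: zero-lag high-pass (30 Hz, net order 4) → rectification →
zero-lag low-pass (2 Hz, net order 2) or moving average (0.25–0.5 s)
→ MVC normalization.

*Zero-lag order-N* is realized as forward–backward application of an
N/2-order Butterworth design (`scipy.signal.filtfilt`), which yields
exactly zero phase and a magnitude response equal to the squared
single-pass response — the only reading that delivers both the stated
order and zero lag with a single design. A `zero_phase=False` switch
runs a causal order-N filter for sensitivity studies. Forward–backward
startup transients are suppressed by `filtfilt`'s reflected padding of
3× the filter length; moving-average edges shrink to the valid window
so the output stays within the input's range. Both edge conventions are
conventions, not physics; they matter only in the first/last fraction
of a second of a trial.

The 2 Hz cut-off is the standard recommendation for slow contractions;
it is the single most force-shaping parameter of the Hill branch
(the envelope essentially *is* the Hill force prediction), and the
comparison deliberately keeps it identical across models.

**MVC normalizers.** The per-muscle envelope normalizer and the torque
normalizer are read off the MVC trial as the **maximum of a 1 s moving
average** of the processed envelope (and of the estimated MVC torque),
not the raw sample maximum. The raw maximum of a stochastic
interference-EMG envelope is an extreme-value statistic, biased upward
by roughly +1.5 standard deviations of the envelope ripple over a
few-second hold (≈ +15 % under the conditions of the synthetic
generator); normalizing by it would systematically deflate every
estimate. The windowed-mean peak is the standard robust MVC reading
and is what the round-trip accuracy figures below are computed with.

## Activation dynamics

$p(t_k)=\gamma e(t_{k-d})-\beta_1 p(t_{k-1})-\beta_2 p(t_{k-2})$ with
$\beta_1=C_1+C_2$, $\beta_2=C_1 C_2$, $|C_{1,2}|<1$,
$\gamma=1+\beta_1+\beta_2$ (unit DC gain). Defaults:

| parameter | default | rationale |
|---|---|---|
| $d$ | 40 ms (rounded to samples) | typical surface-EMG electromechanical delay for lower-limb muscles |
| $C_1=C_2$ | −0.5 | critically damped discrete twitch (double real pole) |
| $A$ | −1.7 | representative subject value; calibrated per subject in use |

The nonlinear shaping $a=(e^{Ap}-1)/(e^A-1)$ amplifies low activation
levels ($a \ge p$ on $(0,1)$ for $A<0$) and is exactly the identity in
the $A\to 0$ limit, handled explicitly. The linear Hill model uses
$a = p$.

## Hill-type contraction dynamics

Muscle–tendon parameters (GAS / SOL): $F_m$ 1600 / 2830 N, $L_{c0}$
5.1 / 3.0 cm, $L_{t0}$ 40 / 26.8 cm, pennation 14° / 30°, tendon
stiffness 180 N/mm, $b=0.5$, $V_{sh}=0.3$. The maximum shortening
speed is not tabulated in the source literature available here;
$v_{max} = 10\,L_{c0}\,\mathrm{s^{-1}}$ is the conventional
fast-muscle scaling and is exposed in the config
(`vmax_Lc0_per_s`).

At each step the tendon force $F_t=k_t(L_t-L_{t0})$ (clipped at 0: a
slack tendon carries no load) must balance $F_c\cos\varphi$; solving
for the required $f_v$ and inverting the hyperbola algebraically gives
$\dot\varepsilon_c$, which is advanced by classical RK4 (default step
1 ms — at least 20× faster than the 2 Hz envelope dynamics, and small
against the ≈ 40 ms linearized approach time constant of the strain).

Two clamps guard the concentric-only force–velocity relation:
$f_v$ is floored at $10^{-3}$ before inversion (pole avoidance at
maximum shortening speed), and whenever the balance would require
$f_v \ge 1$ — i.e. CE lengthening, outside the modeled regime — the
strain is held and $f_v$ clamped to 1. The fraction of steps where the
clamp engages is reported (`fv_clamped_fraction`); during pure
relaxation the force still decays correctly (it is proportional to
$a$), but the strain does not recover until the next contraction. This
is the accepted price of the concentric-only scope and is flagged
rather than hidden.

## Multi-scale cross-bridge contractile element

Two inputs are derived from the *same* EMG: the recruitment rate
$\alpha(t)=p(t)$ (fraction of motor units engaged) and the chemical
input $u(t)$, obtained by thresholding a zero-lag 30 Hz envelope of the
rectified EMG: $\Pi_c = 1$ above threshold, $u = \Pi_c U_c +
(1-\Pi_c)U_r$ with $U_c = 5\,\mathrm{s^{-1}}$,
$U_r = 10\,\mathrm{s^{-1}}$. The threshold defaults to 5 % of the MVC
peak of that envelope — anywhere "a little above baseline" works, since
at low activation the recruitment input is small regardless, and the
sensitivity to the exact value is correspondingly low. The indicator is
shifted by the same electromechanical delay $d$ as the activation
recursion.

With bond-length-independent attachment/detachment rates, the first two
moments of the attached-bridge distribution (aggregate stiffness $k_c$
and force $F_c$) obey closed ODEs — no closure approximation:

$$\dot k_c = -(u+|\dot\varepsilon_c|)\,k_c + \alpha\,k_m(\varepsilon_c)\,\Pi_c U_c$$
$$\dot F_c = -(u+|\dot\varepsilon_c|)\,F_c + \alpha\,F_m(\varepsilon_c)\,\Pi_c U_c + k_c L_{c0}\dot\varepsilon_c$$

with the force–length relation applied at the microscopic scale
(it limits the available binding sites):
$k_m(\varepsilon)=k_{m0} f_l(\varepsilon)$,
$F_m(\varepsilon)=F_{m0} f_l(\varepsilon)$, and
$k_{m0} = 20 F_{m0}$ by default (active stiffness reaching the tendon
stiffness near maximal contraction; it has little influence on the
isometric force output).

**The velocity term in the loss rate is $|\dot\varepsilon_c|$** — the
single most consequential interpretation in this module. Faster
sliding breaks more bridges in *either* direction; the signed form
would make shortening *reduce* detachment. The absolute value is also
what makes the tendon-coupling equation carry its sign factor: from
the series-tendon constraint
$\dot F_c = k_t(L_0\dot\varepsilon - L_{c0}\dot\varepsilon_c)/\cos\varphi$,

$$\dot\varepsilon_c = \frac{k_t L_0 \dot\varepsilon/\cos\varphi + F_c u - \alpha F_m(\varepsilon_c)\Pi_c U_c}{k_t L_{c0}/\cos\varphi + k_c L_{c0} - \mathrm{sign}(T)\,F_c}$$

where $T$ is the numerator; the solution is self-consistent
($\mathrm{sign}(\dot\varepsilon_c)=\mathrm{sign}(T)$) exactly while
$k_t L_{c0}/\cos\varphi + k_c L_{c0} - F_c > 0$, which is checked at
every evaluation. The same convention makes the emergent steady-state
force–velocity relation
$F_c = (\alpha F_m U_c + k_c L_{c0}\dot\varepsilon_c)/(U_c + |\dot\varepsilon_c|)$
a decreasing Hill-type hyperbola in concentric shortening, equivalently
$F_c = \alpha F_m (1 + A_0\dot\varepsilon_c)/(1 - B\dot\varepsilon_c)$
with $A_0 = L_{c0}k_c(0)/(\alpha F_m U_c)$, $B = 1/U_c$.

Integration: classical RK4 from rest $(0,0,0)$, inputs held zero-order
within each 1 ms step, $k_c, F_c$ clipped at zero after each step with
a counter (floating-point undershoot during fast relaxation). The
recruitment input defaults to **continuous** $\alpha(t)=p(t)$; per-phase
hold variants (`hold_at_onset`, `hold_phase_max`), which freeze
$\alpha$ over each $\Pi_c=1$ run, are implemented and selectable — the
per-phase rule is ambiguous for long voluntary efforts where $p$ drifts
within one phase, so the continuous form is the default.

## Huxley PDE oracle

The two-state PDE
$\partial_t n + (S_0/h)\dot\varepsilon_c\,\partial_y n = f(1-n) - gn$,
with attachment confined to $y\in[0,1]$, $f = \alpha f_l \Pi_c U_c$ and
$f+g = u + |\dot\varepsilon_c|$, is integrated by first-order upwind
transport plus an exact exponential reaction substep, under a per-step
CFL check. Its first two moments $k_0\int n\,dy$ and
$k_0 h\int y\,n\,dy$ must reproduce the moment ODEs exactly up to
discretization error, on any drive/velocity history — this is the
package's strongest correctness check for the cross-bridge dynamics
(≈ 0.75 % relative L2 at a 400-point grid and 0.1 ms steps over a 2 s
contraction–relaxation cycle with sinusoidal strain rate).

The sarcomere constants are not separately observable from the
macroscopic aggregates; the oracle uses the consistent set $S_0=L_{c0}$,
$N=1$, $k_0=k_{m0}$, $h=2F_{m0}/k_{m0}$, so its moments land directly on
the muscle scale. Note the advection speed ratio $S_0/h$ is then fixed
at $k_{m0}L_{c0}/(2F_{m0})$ by the aggregates — moment exactness holds
for any such set.

## Synthetic surface EMG

The generator emulates the interference signal of a motor-unit pool
driven by a command profile $c(t)\in[0,1]$:

| parameter | default | meaning |
|---|---|---|
| `fs` | 2048 Hz | acquisition rate |
| `n_motor_units` | 50 | pool size per channel |
| `firing_rate_range` | 8–35 Hz | renewal rate, common-drive modulated |
| `ap_duration` | 8 ms | biphasic waveform (Gaussian derivative) |
| ISI CV | 15 % | renewal variability |
| `noise_rms` | 2 % | Gaussian noise, relative to the full-excitation signal RMS |

Recruitment thresholds are spread uniformly over $[0,1)$; active units
fire as renewal processes at the common-drive rate
$r(c) = r_{min} + (r_{max}-r_{min})c$. Unit amplitudes follow the size
principle (later-recruited units are larger) with the specific profile
derived in closed form from shot-noise statistics so that the
interference variance is proportional to $c^2$ — making the 2 Hz
envelope track the command linearly across the excitation range, which
is the property that gives MVC normalization its meaning. All
randomness flows from a single seed (fixed seed ⇒ byte-identical
trials).

Reference torque for round-trip tests is produced by running a forward
model on the **noise-free command** (recruitment $\alpha = c$,
indicator $\Pi_c = c > 0.01$), so estimator error is separated from
fixture noise.

**What the generator does not emulate:** volume conduction and
electrode geometry, motor-unit synchronization, signal
nonstationarity from fatigue, fiber-type heterogeneity, crosstalk
between channels, and movement artifact beyond white noise. Passing
round-trip tests therefore demonstrates the internal consistency and
noise robustness of the estimation chain under a realistic interference
structure — not accuracy on recorded human data, for which the
envelope–force relationship carries additional physiological
variability.

## Evaluation protocol

Trials carry ground-truth segment labels (mvc, plateau30, plateau70,
fast_short, slow_long) from the generator — windowed metrics use these
protocol labels, never a detector. RMS error is computed on the
MVC-normalized torque scale over the whole trial or a labelled window;
peak error compares window maxima and is insensitive to alignment.
Contribution ratios $F_{m,i}\cos\varphi_i r_i / \sum_j(\cdot)$ are kept
at full precision internally and rounded to two decimals only for
reporting. Shape-factor calibration minimizes MVC-trial RMS by bounded
scalar minimization over $A\in[-3,0)$, with explicit boundary checks
(the bounded minimizer does not probe the boundary itself).

## Problem sizes and numerical defaults

Simulated sessions use 8–20 s trials at 2048 Hz with 50 motor units per
channel; the ODE integrators run at 1 ms steps (0.1 ms where compared
against the PDE oracle, which uses a 400-point bond-length grid).
These sizes were chosen so that the discretization error of every
integration is at least an order of magnitude below the tolerance of
the property it supports.

## Known limitations

- Concentric-only Hill branch: strain does not recover during
  relaxation (flagged via `fv_clamped_fraction`); force is unaffected.
- No eccentric force enhancement, no activation-dependent optimal
  length shift, no non-isometric joint kinematics.
- Single lumped "motor unit" per muscle in the cross-bridge model; a
  population with fast/slow kinetics is out of scope.
- No calcium-concentration dynamics: the contraction/relaxation switch
  is the thresholded-EMG surrogate described above.
- The moment arms are fixed posture-specific constants; no
  angle-dependent regression.
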