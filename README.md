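# emgforce

Estimation of muscle force and isometric joint torque from surface EMG,
for researchers in neuromuscular biomechanics who want to compare
phenomenological (Hill-type) and physiologically grounded (cross-bridge)
contractile-element models on the same signals.

The package targets the ankle plantar flexors — medial gastrocnemius
(GAS) and soleus (SOL) — under isometric contraction, and ships a
motor-unit-based surface-EMG simulator so the whole chain is testable
without recorded data.

## Models

All three estimators share one processing chain and one macroscopic
muscle-tendon structure (contractile element CE in series with a linear
tendon of stiffness $k_t$, pennation $\varphi$, no parallel element):

1. **EMG conditioning** — zero-lag 4th-order Butterworth high-pass
   (30 Hz), full-wave rectification, zero-lag 2nd-order low-pass (2 Hz)
   or moving average, normalization by the MVC-trial envelope peak,
   giving $e(t)$.
2. **Activation dynamics** — a delayed second-order recursion
   $p(t_k)=\gamma e(t_{k-d})-\beta_1 p(t_{k-1})-\beta_2 p(t_{k-2})$
   with $\beta_1=C_1+C_2$, $\beta_2=C_1C_2$, $|C_i|<1$ and unit DC gain
   $\gamma-\beta_1-\beta_2=1$, giving the neural activation $p(t)$.
3. **Contractile element**, one of:
   * **linear Hill** — $F_c = a\, f_l(\varepsilon_c)\, f_v(\dot\varepsilon_c)\, F_m$
     with $a=p$, Gaussian force–length
     $f_l=\exp(-(\varepsilon_c/b)^2)$ and hyperbolic concentric
     force–velocity
     $f_v=V_{sh}(v_{max}+L_{c0}\dot\varepsilon_c)/(V_{sh}v_{max}-L_{c0}\dot\varepsilon_c)$;
   * **nonlinear Hill** — the same with
     $a=(e^{Ap}-1)/(e^{A}-1)$, $-3 \le A < 0$, calibrated per subject on
     the MVC trial;
   * **multi-scale cross-bridge model** — the CE state
     $(k_c, F_c, \varepsilon_c)$ follows the exact first two moments of
     the attached cross-bridge distribution,
     $\dot k_c = -(u+|\dot\varepsilon_c|)k_c + \alpha\, k_m(\varepsilon_c)\,\Pi_c U_c$,
     $\dot F_c = -(u+|\dot\varepsilon_c|)F_c + \alpha\, F_m(\varepsilon_c)\,\Pi_c U_c + k_c L_{c0}\dot\varepsilon_c$,
     driven by a thresholded 30 Hz envelope (contraction indicator
     $\Pi_c$, switched kinetics $u = \Pi_c U_c + (1-\Pi_c)U_r$) and the
     recruitment rate $\alpha = p(t)$.
4. **Joint assembly** — $\tau = \sum_i F_{c,i}\cos\varphi_i \, r_i$ with
   the plantar-flexion moment arms $r$, normalized by the MVC torque.

Because the cross-bridge model drives the force *derivative* with the
neural command, its peak force depends on contraction duration (time
hysteresis): a 0.2 s burst produces markedly less force than a 2 s
effort at the same EMG amplitude, which a memoryless Hill relation
cannot represent. A Huxley two-state PDE solver is included as an
independent oracle for the moment ODEs.

## Worked example

Generate a five-trial synthetic session (MVC, 30 % and 70 % plateaus,
two randomized fast-short / slow-long trials), then compare all three
estimators against the reference torque of one random trial:

```bash
emgforce synth --out trials --seed 1
emgforce compare --trial trials/random1.csv --mvc trials/mvc.csv --out results/random1.csv
```

`results/random1_metrics.csv` then contains (excerpt):

```
segment,model,rms,peak_error
whole,hill_linear,0.0833797,
whole,hill_nonlinear,0.123548,
whole,physio,0.0401403,
fast_short,physio,0.09266,0.0808303
slow_long,physio,0.0523185,0.019695
```

Errors are on the MVC-normalized torque scale (1.0 = MVC torque): the
cross-bridge estimator (`physio`) tracks the reference within 0.04 RMS
over the whole trial, while the Hill variants, fed the very same
envelope, miss the duration-dependent force development of the mixed
fast/slow protocol. `results/random1.csv` holds the full estimated
torque traces for plotting.

The same comparison is available from Python via
`emgforce.estimate_torque` / `emgforce.mvc_reference`, and the shape
factor can be calibrated with `emgforce calibrate-a --mvc trials/mvc.csv`.

## Layout

- `emgforce.series` / `emgforce.emg` — time-series container, EMG conditioning
- `emgforce.activation` — activation dynamics and nonlinear shaping
- `emgforce.hill` — Hill-type CE with series tendon
- `emgforce.physio` / `emgforce.huxley` — cross-bridge moment ODEs, chemical input, PDE oracle
- `emgforce.joint` — torque assembly, metrics, shape-factor calibration
- `emgforce.synth` — motor-unit surface-EMG simulator and protocol fixtures
- `emgforce.config` / `emgforce.pipeline` / `emgforce.cli` — YAML config, end-to-end estimation, CLI

See `docs/methods.md` for the modeling assumptions, parameter defaults
and numerical choices.
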