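# Methods

This note records the model equations as implemented, the parameter
choices that were genuinely open, the numerical conventions, and the
known limitations.  Units throughout: ms, mL, mmHg, μm, μM, mN/mm², cm.

## State and coupling

The coupled state is ten-dimensional: five troponin-system pools
(TSCa₃, TSCa₃˜, TSCa₃*, TS*, TS˜, in μM), the inextensible crossbridge
portions X_p, X_w (μm), free [Ca²⁺] (μM), and the LV and aortic volumes
V_lv, V_a (mL).  Each step evaluates, from pre-step values only:

1. geometry: `R_lv = K_R·V_lv + K_V`, `L = K_L·R_lv + L_b`
   (so dL/dV_lv = K_L·K_R = 0.001956 μm/mL);
2. crossbridge extensions `h_p = L − X_p`, `h_w = L − X_w` and sliding
   `dX/dt = B(h − h_r)`;
3. detachment rates `g = Z_a + Y_v(1 − e^{−γ_m(h_w−h_wr)²})`,
   `g_d = Y_d + Y_c(L−L_c)² + Y_vd(1 − e^{−γ_m(h_w−h_wr)²})`, with
   `γ_m = γ/K_γ` while the weak crossbridges lengthen (dX_w/dt > 0) and
   `γ_m = γ` otherwise;
4. the five-pool kinetics (binding `Y_b·[TS]·[Ca]³`, attachment
   `f·e^{−R(L−L_a)²}`, the weak↔power exchanges, detachment g, g_d);
5. Ca²⁺ balance `d[Ca]/dt = Q_rel − Q_pump − ν·I_troponin` with the
   release pulse `Q_rel = Q_m (t/t₁)⁴ e^{4(1−t/t₁)} + Q_pump,rest`
   retriggered at each cycle start, uptake
   `Q_pump = K_p/(1+(K_m/[Ca])²)`, and I_troponin the net flux of
   systems into the Ca-bound pools;
6. forces `F_b = A_w(TSCa₃˜+TS˜)h_w + A_p(TSCa₃*+TS*)h_p`, piecewise
   passive force F_p (linear compressive below the slack length
   L₀ = 1.043 μm, exponential above), `F_ext = K_S·F_b + F_p`;
7. Laplace `P_lv = 2K_u·F_ext·h_lv/R_lv` (h_lv = 1.35 cm constant),
   `P_a = V_a/C_a`, diode flows, and the volume derivatives.

All ten components are then updated simultaneously (forward Euler).

### The γ_m branch

The printed form of the detachment modification is typographically
ambiguous.  We implement attenuation during *lengthening*: K_γ = 85.3
divides the extension sensitivity when dX_w/dt > 0.  Rationale: the
factor exists to stop the strong extension-dependent detachment from
destroying the filling phase, and lengthening is the filling-phase
signature.  During shortening (ejection) the full γ applies, which is
what produces the velocity-dependent force drop that this analysis is
about.  The branch is a one-line strategy in the kernel and reference
module if the opposite reading ever needs testing.

### Ca²⁺ stoichiometry and TS_tot

Two constants of the cell model are not available from the printed
tables and had to be fixed by the package:

* **ν (`cell.ca_stoich`), default 3.**  Each cooperative troponin
  system binds three Ca²⁺ ions, so the Ca²⁺ balance must subtract three
  ions per system entering the bound pools.  The alternative 1:1
  bookkeeping makes the released Ca²⁺ (∫Q_rel ≈ 32.8 μM per beat)
  over-buffer: activation front-loads, the ventricle ejects to
  ESV ≈ 11 mL, and the late isochrone intercepts go negative — far
  outside the physiological behaviour the model is known to produce.
  With ν = 3 the limit cycle lands on the published operating point
  (onset volume 126.46 mL, peak P_lv ≈ 107 mmHg, SV ≈ 76 mL).
* **TS_tot = 23.3 μM.**  One system is three troponins; the
  physiological ~70 μM troponin concentration gives 70/3 ≈ 23.3 μM of
  systems.  The simulated isochrones are only weakly sensitive to this
  value (halving it moves the slopes by <2%) because the bound pool is
  release-budget-limited, but 23.3 also reproduces the published onset
  volume to 0.03%.

### Aortic compliance

C_a is fixed at clamp_Va/clamp_P = 105/70 = 1.5 mL/mmHg, the unique
value consistent with `P_a = V_a/C_a` at the clamp point.  Offset
(`unstressed-volume`) compliance variants were explored and rejected:
they distort the pressure course without improving anything.

## Protocols

* **Ejection-onset clamp.**  At the first upward crossing of 70 mmHg in
  each cycle, V_a is reset once to 105 mL (so P_a = 70); V_lv is never
  reset, and all variables evolve freely afterwards.  A hold variant
  (P_a pinned for the rest of the cycle) exists behind
  `circulation.clamp_hold` but is not used by any reported number.
  On the limit cycle the onset state is afterload-independent to
  4 × 10⁻⁶ relative in V_lv.
* **Volume-drop elastance (E_inst).**  At t_ej + Δ the run is branched;
  the branch has V_lv reduced by 0.25 % with concentrations and X_p,
  X_w frozen (attachment states cannot jump).  Both branches advance
  one 0.01 ms step and E_inst = ΔP_lv/ΔV_lv between them.  Reading ΔP
  at the next step rather than instantaneously lets the sliding
  elements relax for one step; the difference is <0.5 %.
* **Isochronous fits (E_load, k_a).**  Each afterload run contributes
  its sample at its own t_ej + Δ; ordinary least squares (centered
  closed form — the raw normal equations lose ~7 digits on the tightly
  clustered abscissae of late isochrones) gives the slope, and
  V₀ = −intercept/slope.  End-systolic E_load can also be taken at each
  run's own aortic-closure time, since end-systole shifts slightly with
  afterload.
* **Isovelocity shortening.**  Cell-only: [Ca²⁺] clamped at 0.3 μM
  (within the coupled model's ejection-phase range, which decays from
  0.83 μM at onset to 0.28 μM at +280 ms), L held at the ejection-onset
  length 1.09717 μm for 100 ms, then shortened at 0.1/0.15/0.20 μm/s
  (taken literally in μm/s; the coupled model's ejection dL/dt spans
  0.1–0.9 μm/s, the same range).  After the ~2 ms transient h_p sits on
  the closed form h_p,ss = (dL/dt)/B + h_pr, which is the whole content
  of the model's force–velocity relation.
* **TVEM comparator.**  The LV is replaced by
  P_lv = E(t)(V_lv − V₀) with the three-branch cosine waveform
  (E_d → E_s over T_s = 0.3·T_rr, back to E_d by 1.5·T_s) inside the
  same circulation and integrator.  Defaults E_s = 2.5 mmHg/mL and
  V₀ = 15 mL follow the Heldt-type lumped models; E_d = 0.10 mmHg/mL
  (0.13 in Heldt) keeps the 5–200 ms isochrone window on the rising
  limb of E(t) given the emergent onset time (~105–116 ms).  Because
  E depends on absolute cycle time and the TVEM onset times spread
  across afterloads (the long isovolumic phase lets P_a drain below
  70 mmHg, so ejection can begin before the clamp), TVEM isochrones are
  taken at a *common* absolute instant (first run's onset + offset).
  With that convention the identity E_load = E_inst = E(t) and exact V₀
  recovery hold to machine precision — the structural contrast with the
  crossbridge ventricle, where no common (E(t), V₀) pair exists.

## Numerics

* Fixed-step forward Euler, dt = 0.01 ms (reference value; configurable,
  trajectories converge at O(dt)).  The stiffest term at the operating
  point is `Z_r·[Ca]³ ≈ 4 ms⁻¹`, comfortably stable at 0.01 ms.
* Concentrations that undershoot zero are clipped with a warning; at
  the reference dt no clips occur.
* Limit cycle: cycles repeat until |ΔEDV| < 10⁻⁴ mL between consecutive
  cycle starts (max 100).  The attractor is strongly contracting — the
  default conditions converge in 3–4 cycles, and tightening the
  tolerance to 10⁻¹⁰ changes no reported digit.
* Rate diagnostics (dF_ext/dt vs dL/dt) use centered differences with a
  1 ms stencil, wide enough to smooth Euler noise without biasing the
  slope; pointwise dL/dt uses the ±1-step stencil.
* Problem sizes: one cycle is 10⁵ steps; the full five-afterload study
  is ≲3 × 10⁶ steps and runs in seconds through the JIT kernel.  The
  kernel duplicates the reference formulas for speed; a test asserts
  one kernel step equals the composition of the reference operations to
  1e-13.

## What the closed-form approximations do and do not capture

* The E_inst closed form
  `2K_u·h_lv·K_L·K_R·K_S·A_p·(TSCa₃*+TS*)/R_lv` underestimates the
  measured value by 15–25 % because it drops the weak-state stiffness
  `A_w(TSCa₃˜+TS˜)`, which is not negligible during early ejection; its
  *shape* (the Ca²⁺-driven bell) is faithful.
* The initial-E_load estimate built from ΔL = ½·L̇·Δt and
  ΔF_ext = A_p·(power)·L̇/B is an order-of-magnitude device only: it
  omits K_S and assumes the velocity spread across afterloads persists
  over Δt, while in the coupled model that spread decays.  Both the
  assembled form and its collapsed version (which differ by an exact
  factor 4) are reported by the API; neither feeds any headline number.

## Limitations

* The shortening-transient gap |h_p − h_p,ss|/h_p,ss at t_ej + 15 ms
  evaluates to ~0.9 % here; it is a second-order quantity (the
  quasi-steady lag ∝ d²L/dt²) and is sensitive to the exact early
  ejection flow-acceleration profile in a way the isochronous tables
  are not.
* No baroreflex, no inotropic modulation, fixed cycle length, constant
  wall thickness, linear V–R and R–L maps: the model is a measurement
  instrument for the elastance question, not a general hemodynamics
  simulator.
* Valves are ideal diodes without inertance or regurgitation.
* The step-2 linearity analysis is exercised only as a numerical
  diagnostic (the dF_ext/dt vs dL/dt fit); no symbolic constants are
  extracted.
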