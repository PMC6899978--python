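# Methods

`girfpulse` designs simultaneous multi-slice (SMS) refocusing RF pulses
jointly with their slice-select gradient waveform, treating the gradient
chain as a linear time-invariant (LTI) system.  This note records the
models, the numerical choices, and the limits of what the tests show.

## Physical model

**Spin domain.**  The magnetization dynamics are propagated in the spin
domain: each raster interval of length τ applies an SU(2) rotation with
Cayley–Klein parameters

    α = cos(φ/2) + i γτ w sin(φ/2)/φ,
    β = i γτ B1 sin(φ/2)/φ,
    φ = −γτ √(|B1|² + w²),

where `w = z·G̃(t) + 2π ΔB0/γ` is the local field along z (T-equivalent)
and `B1` the complex RF sample (T).  States start at (a, b) = (1, 0);
relaxation is neglected, which is appropriate for pulses of a few
milliseconds.  The crushed spin-echo observable is `|b|²` with phase
`arg b²`; low-tip excitation behavior is evaluated as the flip angle
`asin |2 a b*|`.  `sin(φ/2)/φ` is evaluated by series below |φ| < 1e−8
(forward) / 1e−4 (derivative path); both switches are far below the
rounding floor of the surrounding arithmetic.

**Gradient system.**  The demanded gradient `Gs` maps to the realized
gradient by multiplication with a tabulated transfer function H(f) in the
frequency domain.  Filtering zero-pads to at least twice the signal
length (next power of two) — physically, the gradient is off before and
after the pulse — interpolates H linearly (real and imaginary parts) onto
the transform frequencies, and takes H ≡ 0 outside its tabulated band
(measured gradient chains are low-pass).  The discrete filter is also
materialized as a dense Toeplitz operator with its transpose for the
chain rule; operators are cached per (transfer function, grid) and
results are independent of caching.  Hermitian symmetry of loaded
two-sided responses is enforced by averaging H(f) with conj(H(−f)) so
impulse responses are real.  Synthetic responses use a Butterworth
magnitude `(1+(f/fc)^{2n})^{−1/2}` with a pure delay phase; they emulate
the low-pass character and delay of measured whole-body gradient chains
but none of their mechanical resonance ripples.

## Design problem

Controls are the RF amplitude r, RF phase ϑ and slew rate s per raster
interval; the gradient is the running integral of the slew starting at 0.
Hard box bounds (0 ≤ r ≤ rmax, |s| ≤ smax, |ϑ| ≤ π) are enforced by
projection/solver bounds and hold exactly in every exported waveform.
The demanded gradient amplitude (|Gs| ≤ Gmax), the refocusing-profile
magnitude errors (out-of-slice `|b|² ≤ e_out`, in-slice `1−|b|² ≤ e_in`,
transition bands unconstrained) and the per-slice phase spread
(|φ − φ̄_l| ≤ e_p, with φ̄_l the argument of the mean in-slice phasor,
wrap-safe) are handled by even-power penalties of the normalized
residuals added to the duration-plus-RF-energy cost

    J = T + (τ μ_RF/2) Σ r²
        + (τ μ_G/p) Σ (Gs/Gmax)^p
        + (δ μ_out/2p) Σ_out (|b|²/e_out)^p
        + (δ μ_in/2p) Σ_in ((1−|b|²)/e_in)^p
        + (δ μ_p/p) Σ_l Σ_in ((φ−φ̄_l)/e_p)^p .

The exponent p (even, 2 → 32 by doubling) pushes the penalties toward
max-violation (L∞) behavior; the weights re-balance every 20 optimization
steps: ×2 for a violated group, ÷1.25 for one comfortably inside its
bound (residual below −0.1× bound), clamped to [1e−6, 1e9].  The global
SAR estimate `SAR_e = SAR_eff · f_p · τ Σ r²` (r in µT) is tracked and
doubles μ_RF when it exceeds the configured limit; with the default head
coil parameters (f_p = 16.67 1/s, 0.25 W/kg/µT², limit 3.2 W/kg) the
designs stay far below the limit and the rule never fires in practice.

**Gradients.**  All first derivatives are exact adjoints: the state
recursion is complex-linear in (a, b), so the reverse sweep propagates a
complex cotangent with the conjugate-transposed step matrix and
accumulates Re(g^H (∂M/∂q) u) per control; the derivative with respect to
the realized gradient is pulled back through the filter transpose and the
transpose of the slew integration (reversed cumulative sum).  The phase
penalty couples positions through the per-slice mean; its derivative
includes the mean-phase term `∂φ̄/∂φ(z) = Re(e^{iφ(z)}/Σ e^{iφ})`.
Agreement with central finite differences is at the finite-difference
noise floor (≲ 5e−7 relative at the optimal step).

## Solver

The lower level minimizes J at fixed duration with box-constrained
limited-memory BFGS (projection via the solver's bound handling,
memory 20), run in rounds of 20 iterations between weight adaptations;
the objective is rescaled to O(1) per round so the line search is immune
to the large penalty weights.  In real-valued mode the signed amplitude
is optimized directly within [−rmax, rmax] (a negative value stands for
phase π), so sub-pulse polarities can flip continuously through zero —
freezing the sign pattern instead traps the search in the initialization
topology.  The exponent p doubles when the iteration stagnates (relative
per-round decrease < 1e−5) or the maximal violation stops improving,
but only once residuals are at the scale of the bounds; sharpening
earlier stalls the line search.  Feasibility means every residual
≤ 1e−3 absolute.

The upper level shrinks the number of raster samples geometrically
(default factor 0.97) while the re-solved problem stays feasible, then
bisects between the last feasible and first infeasible counts down to one
raster sample.  Warm starts exploit the exact time-rescaling invariance
of the Bloch dynamics — playing the same pulse a factor ρ faster with
B1/ρ and slew/ρ² reproduces the same profile — with the hardware
projection clipping whatever exceeds the limits; that clipping is exactly
what each re-solve must repair, which is why small steps are the default.
If a shrink step fails from the previous solution's basin, it is retried
once from the rescaled initial-duration solution, whose larger hardware
margins tolerate rescaling better.  The pipeline is deterministic: two
runs from the same inputs produce identical reports.

## PINS initialization

The initial guess is a PINS pulse: N hard RF sub-pulses (gradient off)
interleaved with N−1 minimum-time gradient blips whose zeroth moment
advances the periodic pattern by one cycle per slice spacing
(spacing = FOV/MB, slices uniformly spaced).  N = ceil(TBWP·spacing/THK).
For even MB the sub-pulse signs alternate, shifting the periodic profile
by half a period so the slices sit at odd half-multiples of the spacing.
Because RF and gradient never overlap, the hard-pulse Shinnar–Le Roux
(SLR) model is exact for PINS, and the sub-pulse envelope comes from FIR
design plus the exact inverse hard-pulse recursion:

- The β prototype is a linear-phase weighted-least-squares FIR (designed
  on a dense grid; supports even tap counts — type II — which the PINS
  sub-pulse counts require), band edges at (1 ∓ w)·TBWP/2 bins with
  w = D∞(d1, d2)/TBWP clamped at 0.9, weights (1, d1/d2), and passband
  target 1 (full inversion).  Default ripples d1 = 0.01/4, d2 = 0.01/2.
- α is the minimum-phase spectral factor of 1 − |β|², computed
  cepstrally with a floor of 1e−12 on 1 − |β|² where least-squares
  ripple pushes |β| marginally above 1.
- The signed flip angles follow from the exact inverse recursion; each
  sub-pulse is played at the common minimum duration allowed by the peak
  flip at rmax, rounded up to the raster; blips are midpoint-sampled
  minimum-time triangles (trapezoids when Gmax binds) rescaled to exact
  moment.

**Convention validation.**  The exact sub-pulse scaling used in published
PINS refocusing initializations is not printed anywhere; two defensible
conventions differ materially.  Rescaling β to unit peak before the
factorization (the common rf-tools behavior) yields durations 12–23%
shorter than the published initializations, while the full-inversion
passband with a tiny factorization floor reproduces the four published
durations to −1.6% / −2.0% / −2.3% / −3.5% and the published initial
profile error (≈0.012 vs 0.010).  The latter is therefore the package
default.  Its trade-off: the RF energy is higher, so the SAR estimate of
the MB=5 / 2 mm initialization computes to ≈0.79 W/kg against the
published 0.61 W/kg; sweeping the factorization floor traces a (T, SAR)
curve on which the published pair does not lie, so no single convention
reproduces both.  The durations (and the profile error) carry the
validation weight here.  The minimum-phase α also makes the flip train
slightly asymmetric, which leaves a small in-slice phase spread
(~0.06 rad) in the initialization; the optimizer removes it when phase
constraints are active.

## Synthetic data and what the tests show

No measured transfer functions ship with the package; tests and examples
run on synthetic Butterworth low-pass responses with cutoffs at the
published y/z-axis values (4.2 / 3.75 kHz) and a 50 µs delay.  These
reproduce the two leading effects of real gradient chains — bandwidth
truncation and temporal shift — but not measurement noise, mechanical
resonances, or axis cross-terms (the model is deliberately one-axis LTI).
Passing the desk-scale compensation test therefore demonstrates the
mechanism (an idealized design breaks under the filter, a filter-aware
design does not) rather than scanner-grade fidelity.

Desk-scale problem sizes (two slices over 60 mm, 256 spatial points,
12.8 µs raster) were chosen so the full bilevel design runs in minutes on
one core; the published full-scale cases (five slices, 6.4 µs raster,
~1000 spatial points) use the same code path and only larger grids.  The
minimum durations this solver reaches are somewhat longer than a
second-order semismooth-Newton lower level would find; the bilevel
contract here is first-order stationarity of each accepted solve, not
iterate-for-iterate equivalence with any particular Newton scheme.

## Degenerate inputs and tie-breaks

- φ → 0 rotation steps take the limit (α, β) = (1, 0); derivative
  formulas divide by max(q, tiny) and recover the correct limits.
- arg b² is undefined at b = 0; such positions contribute no phase
  penalty and no phase cotangent (in-slice b ≈ 1 in any feasible
  region, so this only matters for pathological starts).
- Slice domains on coarse spatial grids always contain at least the grid
  point nearest each slice center, so phase means are well defined.
- The duration bisection prefers the longer duration on ties (it keeps
  the last feasible count).

## Known limitations

- One gradient axis; no cross-terms, B0 eddy-current terms, thermal or
  non-LTI amplifier behavior; ideal RF chain.
- Relaxation neglected; no pTx, no spatially varying B1 maps (global B1
  scale and B0 offset sweeps only).
- The SAR discrepancy of the initialization convention described above.
- The lower level is first-order; very aggressive duration targets can
  stall at a plateau a second-order method would pass.
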