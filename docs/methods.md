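# Methods

## Model and assumptions

`cochleanet` models the unwrapped cochlea as a one-dimensional resistive
ladder. The lumen is a straight tube of circular cross-section whose
diameter tapers linearly from 2.0 mm at the basal opening to 1.0 mm at the
apex over 32 mm, discretized at a uniform 0.25 mm step (129 nodes). The
step is chosen so that every electrode (≈1 mm pitch) and recording wire
(2 mm pitch, first wire at 1 mm) lands exactly on a node; off-node
positions are snapped to the nearest node (ties toward the base) with a
warning. The linear-diameter taper is an acknowledged stand-in for the
digitized human cross-section profile; a measured `(position, area)` table
can replace it through the `table` taper and the YAML config.

Electrical elements, all per the quasi-static, purely resistive limit:

- **Longitudinal**: each inter-node saline segment contributes
  `R = Δx/(σ·A_mid)` with `A_mid` the mean of the end-node areas. Units are
  fixed so mm, mm² and S/m combine to kΩ. Default saline conductivity is
  1.6 S/m, a standard room-temperature value for 1 % w/v NaCl
  (≈ 0.171 mol/L); it is exposed in the config because the solution recipe,
  not the conductivity, is the primary specification.
- **Transverse**: one cross-wall resistance per node to a single ideal bath
  node at 0 V, default 47 kΩ everywhere — the reference ("calibrated")
  configuration. `inf` removes the pathway and yields the insulating-wall
  variant.
- **Boundaries**: the basal opening (2 mm stub at the basal area) and the
  apical flushing tube (0.011-inch bore, 20 mm assumed effective length)
  are modelled as fluid-column resistances to the bath; both overridable,
  since the tube's electrical length is not knowable from its bore alone.

The bath is a single ideal node: return paths from all wall positions to
the remote case ground are taken as similar, and any bath spreading
resistance is absorbed into the transverse values. Electrodes are ideal
point current sources; there is no electrode–electrolyte interface element.
This is why the simulated trans-impedance matrix carries `diagonal_valid =
False` flags rather than modelled diagonal entries, mirroring the clinical
situation in which the stimulating contact's own reading is contaminated by
interface voltage. The solve is steady-state (no RC transient); biphasic
pulses enter only through the convention that the reported peak-to-peak
value is twice the leading-phase voltage, signed so the center contact's
response is positive and sink-dominated wires show inverted polarity.

## Stimulation and metrics

`StimulusSpec` fixes mode (MP/BP/TP/pTP), center contact (default 8),
intracochlear sinking fraction σ, sink offset n (contacts skipped between
center and each sink), amplitude (default 800 μA) and phase duration
(metadata only). pTP(σ=0) and pTP(σ=1) are definitionally identical to MP
and TP and produce bit-identical current vectors. BP's single sink defaults
to the basal side (higher contact number), exposed as a flag because the
bipolar profile is intrinsically asymmetric.

The focusing parameter α (dB/mm) is the origin-constrained least-squares
slope of `L(x) = 20·log10(|V(x)|/|V_peak|)` against distance from the peak
wire, pooled over both sides by default, with configurable options for
per-side fits and excluding the peak wire. Wires more than 40 dB below the
peak are dropped as a numerical-noise guard (configurable). Magnitudes are
used so polarity-inverted wires near sinks contribute by size; the count
and positions of sign flips are recorded on the fit. R² is computed on the
dB scale. All-equal profiles are flagged `flat` (α = 0, R² reported as 1)
rather than fitted. α is invariant under uniform scaling of the profile, so
normalization (division by the largest magnitude) never changes it.

The exact functional form of the bench's decay fit is not public; the form
above is declared once and used identically across every mode and σ so that
α values are comparable — which matters more for the trade-off curves than
the absolute numbers.

## Superposition sweeps

Because the network is linear, the pTP(σ) field is exactly
`(1−σ)·MP + σ·TP+n` per wire; `tradeoff_curve` therefore solves the two
endpoints once and sweeps σ by mixture (default grid 0…1, step 0.005 —
sub-5 % resolution is needed because the focusing curve steepens past
σ = 95 %). The linearity of max V_SI,pp in σ is asserted inside the sweep,
not assumed. The knee is the σ at the largest forward finite difference of
α(σ); ties break to the largest σ with a warning. Note that in a purely
simulated twin both mixture endpoints are simulated, whereas the bench
mixed measured endpoints — the identity is exact here and only approximate
there.

## EFI simulation and calibration

`simulate_efi` performs 16 monopolar probes (32 μA default, amplitude
cancels) and samples all contact positions, giving a symmetric
(reciprocity) 16×16 trans-impedance matrix. Calibration minimizes the
root-mean-square difference, in percent, between normalized profiles
(each scaled to its largest valid entry — profile *shape*, matching how
physical resistor values are chosen against in-vivo telemetry), excluding
diagonal entries. Optimization is in log10-resistance space over bounds
[1 kΩ, 1 MΩ]: a fixed 25-point coarse grid provides a deterministic
multi-start, followed by bounded scalar refinement (shared mode) or
L-BFGS-B over all nodes with a smoothness penalty
`λ·Σ(Δ log R)²`, λ = 0.1 by default (per-node mode). The penalty encodes
that neighbouring wall segments are electrically similar; it biases
per-node fits toward smooth profiles, which is why per-node self-recovery
is tested for direction (monotonicity) rather than exact values. The
accepted-objective history is returned for monotonicity checks. The 47 kΩ
default is treated as the reference value, not as a recoverable target: the
in-vivo profile it was tuned against is not available.

## Synthetic telemetry

`make_invivo_like_efi` builds a ground-truth model by jittering each node's
transverse resistance log-normally (resistor tolerance, default 5 % — a
typical discrete-component grade), simulates its EFI, corrupts every entry
with independent unit-mean log-normal measurement noise (default CV 3 % —
chosen to be visible yet recoverable; bench replicate scatter is shown as
error bars but never tabulated), and averages the replicates (default 3).
`make_noisy_siv` does the same for wire profiles, returning per-wire
replicate standard deviations. All draws come from one
`numpy.random.default_rng(seed)`; identical noise specs give bit-identical
outputs, and CV = 0 short-circuits to the exact noiseless values.

The generated EFI reproduces the two qualitative signatures of in-vivo
telemetry on the default taper: inverted-V rows peaking at the stimulating
contact, and profiles flatter apically than basally (less conductive
electrolyte apically keeps the potential up). What it does *not* emulate:
electrode–electrolyte interface drift, spatially correlated noise, bath
geometry effects, or any neural response. Passing recovery tests therefore
show the estimator is consistent under the declared noise model, not that
it is robust to everything a clinic would see.

Parameter recovery behaves differently depending on where the randomness
lives. With a *shared*-resistance truth and measurement noise only
(CV 3 %, 3 replicates), shared calibration recovers the truth to well
within 5 %. With per-node truth scatter at the 5 % tolerance default, no
shared value reproduces the scattered model's EFI shape exactly; the
shared fit then tracks the truth's geometric mean with a residual scatter
of roughly 2–3 % (occasionally beyond 5 %). The suite pins the latter chain
at fixed seeds and treats the former as the recovery guarantee.

## Numerical choices

- Grounded nodal analysis with dense Cholesky factorization (129×129 at the
  default step), cached per network; a factorization failure is reported as
  a floating network (no path to ground). Solutions are verified against a
  1e-9 relative residual.
- Determinism: no randomness anywhere outside `NoiseSpec`; repeated runs
  are bit-identical within a session.
- Degenerate inputs: all-zero profiles, off-array sinks, non-positive
  dimensions, uncovered area tables, unbalanced current vectors and
  non-finite calibration targets all raise typed validation errors;
  missing-sink errors name the offending contact number.
- Peak ties in `max_siv` resolve toward the stimulating contact when the
  profile carries stimulus metadata, else to the basal-most tied wire.

## Known limitations

The 1-D collapse makes current sinks perfect point absorbers: tripolar
profiles fall by >20 dB within one wire spacing of the flanks, more sharply
than a physical bench, where finite contact area, the silicone carrier and
3-D spreading soften the notch. Consequences documented by the test suite:
the dB-scale focusing fit has low R² for high-σ tripolar-like profiles
(the profile is genuinely not single-exponential there), the fitted α gap
between TP+0 and TP+2 is wider than measured on a bench, and the MP-to-TP+2
amplitude ratio comes out near 2.5 rather than 3.5. Trends — mode
orderings, the monotone amplitude/focusing trade-off in σ, the σ > 95 %
knee, and TP+2's higher amplitude at comparable focusing — are reproduced.
The reproduction bundle (`cochleanet reproduce`) uses the default problem
sizes throughout: 129-node network, 201-point σ grids, three calibration
seeds; the whole bundle takes seconds on one CPU.
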