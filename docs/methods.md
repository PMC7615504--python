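# Methods

This note documents the models, numerical choices and limitations behind
`heatsens`: what exactly is computed, under which assumptions, and what
the synthetic generators do and do not emulate.

## The sensitivity comparator M

For a heat stress index *U*(*T*, *h*) the marginal temperature-equivalent
change is

    M(T, h) = (∂U/∂T) / (∂U/∂h)      [% RH per °C]

interpreted as the relative-humidity change producing the same change in
*U* as a 1 °C warming.  Geometrically it is the (negated) slope of the
index's isopleth through (*T*, *h*).  Because *M* is a ratio of partials
of the same function, it is invariant under any strictly increasing
rescaling of *U* — this is what makes indices on incomparable scales
comparable, and it is asserted as a test invariant (≤ 2 % relative
deviation at the default steps, the residual being pure
finite-difference error).

Partials are estimated by **forward differences** with steps
δT = δh = 0.1 (°C, % RH).  Rationale for 0.1: the wet-bulb solver is
converged to 0.01 °C, so differences over steps two orders of magnitude
larger are not corrupted by iteration noise, while the indices are smooth
enough that first-order truncation error is negligible at this scale.  A
central-difference mode exists as a consistency oracle; tests verify the
forward/central gap halves when the step halves.  Conventions:

- The forward difference is (U(T+δT) − U(T))/δT.  (With the opposite
  ordering every *M* would flip sign; the convention here keeps *M*
  positive for heat indices, matching the interpretation above.)
- At the saturation boundary *h* = 100 % a forward humidity step would
  supersaturate; a backward step is taken and flagged.
- If ∂U/∂h = 0 (an index locally flat in humidity, e.g. any purely
  temperature-dependent index), *M* is reported as a flagged infinite
  sentinel, not an error, so grid computations render rather than crash.
- ΔM between two indices is only defined where both *M* values are
  finite; it is exactly antisymmetric.

Grid computations (`m_grid`) mask cells with distinct codes —
`INDEX_UNDEFINED`, `M_INFINITE`, `OUTSIDE_ENVELOPE`, `ENVELOPE_NO_DATA` —
so downstream plots can hatch each differently.  The default lattice is
T ∈ [0, 50] °C in 0.5 °C steps, h ∈ [1, 100] % in 1 % steps.

The same procedure applies with any other humidity coordinate.  At a
fixed state, switching from relative to specific humidity divides every
index's *M* by the same positive factor (dh/dq at that state), so
cross-index comparisons are representation-independent; comparisons of
one index *across temperatures* are not, because Clausius–Clapeyron makes
dh/dq temperature-dependent.  Wind- or radiation-space sensitivities are
structurally possible through `AirState` but not shipped as operations.

## Index implementations

All evaluators are pure functions of an `AirState` (T °C, RH %, wind
0.5 m/s default, mean radiant temperature defaulting to *track* the air
temperature, pressure 101.325 kPa default).  Each returns a value plus an
explicit defined/undefined flag with a reason code; nothing extrapolates
silently.

**Saturation vapour pressure** uses Buck (1981) over liquid water,
e_s = 0.61121 exp(17.502 T / (240.97 + T)) kPa, valid −40…60 °C.  The
choice is isolated behind one function so an alternative (e.g. Bolton)
could be swapped; all index formulas and all test golden values derive
from this same curve.  Ice-phase saturation and altitude-dependent
pressure are out of scope.

**WBT** is the thermodynamic wet-bulb temperature in the Davies-Jones
sense: the temperature at which a *saturated* parcel at the same pressure
has the same Bolton (1980) equivalent potential temperature θ_E as the
actual parcel.  It is found by bracketed Brent root-finding on θ_E
(tolerance 10⁻³ °C, well under the documented 0.01 °C), with the
saturated branch short-circuited.  This pseudoadiabatic definition sits a
few tenths of a degree below the isobaric psychrometric-balance wet bulb
in hot dry air; the test suite carries an independent psychrometric-
balance bisection oracle and allows 0.5 °C for that definitional gap.
Because the implementation inverts θ_E, adiabatic evaporation (constant
θ_E) leaves WBT constant by construction — the property that makes WBT
blind to direct moisture addition — and a test verifies this to 0.05 °C
along independently constructed adiabatic paths.

**HI** follows the NOAA specification exactly: Steadman's simple average
0.5 (T + 61 + 1.2 (T − 68) + 0.094 RH) in °F; when it reaches 80 °F the
Rothfusz regression applies, with the published low-RH (RH < 13 %,
80–112 °F) and high-RH (RH > 85 %, 80–87 °F) adjustment terms.  Note the
below-threshold branch is a blend, not exactly the air temperature; the
paraphrase "HI equals T below 26.7 °C" is only approximately true, and
its humidity slope (0.047 °F per % RH) is why M_HI is large-but-finite
(≈ 42 at 20 °C/50 %) rather than infinite in the cool regime.

**Humidex** is T + 0.5555 (e − 10) with e the dewpoint-derived vapour
pressure in hPa.  With the analytic dewpoint inverse, e(esat(dewpoint))
equals the ambient vapour pressure exactly, so it is computed directly.
Undefined at RH = 0 (no dewpoint).

**AT** is Steadman's shaded apparent temperature including wind:
T + 0.33 e − 0.70 v − 4.00, e in hPa, v in m/s.  **sWBGT** is
0.567 T + 0.393 e + 3.94, e in hPa.  Both formulas exist in several
unit dialects in the literature; the hPa dialects adopted here are the
standard ones, fixed once in the code, and every golden value in the
tests is generated from them, never from published figures.

**UTCI** evaluates the published 210-term 6th-order polynomial in
(T_a, v_a, T_mrt − T_a, p_a), with coefficients stored in the
operational ordering in `_utci_coeffs.py`.  The published validity box
is enforced: T_a ∈ [−50, 50] °C, vapour pressure ≤ 5 kPa, wind
∈ [0.5, 17] m/s, T_mrt − T_a ∈ [−30, 70] K; outside it the evaluator
returns flagged-undefined with a specific reason (`T_LIMIT`, `VP_LIMIT`,
`WIND_LIMIT`, `TMRT_LIMIT`) — masking, never clipping, because a clipped
UTCI silently misrepresents exactly the hot-humid extremes where indices
disagree most.  The transcription is verified by the defining property of
the UTCI scale: on the reference line (v_a = 0.5 m/s, T_mrt = T_a,
RH = 50 % below 29 °C / p_a = 2 kPa above) UTCI equals T_a up to
polynomial fit error; residuals are within ±1.3 K over −30…50 °C, and a
test asserts ±2 K.  Temperatures in [−50, −40) °C are inside the nominal
UTCI box but below the saturation-curve fit domain and are reported as
out-of-range; irrelevant for heat stress.

**WBGT-indoor** (no radiation term) is Lemke & Kjellstrom's form
0.67 T_w + 0.33 T_a − 0.048 log₁₀(v) (T_a − T_w), evaluated at the
package-wide wind default, a convex blend of WBT and T for all realistic
winds.  **Ts** is WBT + 4.5 (1 − h²) with *h* the *fractional* relative
humidity — the offset form is only physically sensible on 0–1, spanning
+4.5 °C in dry air to 0 at saturation, even though the rest of the
package quotes humidity in percent.

Fixed assumptions throughout the comparisons: 10 m wind 0.5 m/s (the
minimum UTCI reference wind) and mean radiant temperature equal to air
temperature.  Because `AirState` stores an *unset* radiant temperature as
"tracks T", temperature perturbations move T_mrt with T — the derivative
∂UTCI/∂T is taken along the T_mrt = T + const line, which is the intended
reading of the fixed-relationship assumption.  Outdoor WBGT with a
black-globe term, free radiation/wind fields, and physiological
heat-balance models are non-goals.

## Isopleths

`trace_isopleth` evaluates the index on a grid (undefined cells as NaN)
and extracts the level set by marching squares (scikit-image
`find_contours`), interpolating linearly along cell edges.  Every
returned point therefore re-evaluates to the level within a tolerance
that shrinks with the grid; on the default grids it is ≤ 0.05 index
units, which the suite self-checks on every traced contour.  Branches are
oriented so humidity is monotone from first to last point; disjoint
branches are allowed; an unbracketed level returns an empty, flagged
result rather than an error.

## Climate envelope

The envelope records, per 1 %-wide relative-humidity bin, the maximum
co-occurring dry-bulb temperature, and classifies any state as inside,
exceeding, or in a bin with no data (no-data bins count as outside —
conservative masking — but carry a distinct code).  The upper bound is
closed: T equal to the bin maximum is inside.

`build_envelope` accepts any (T, h) sequence, so a real reanalysis scan
(e.g. hourly 2 m temperature and derived RH over decades) can feed it;
how such a scan weights space or restricts to land is the caller's
choice.  The **synthetic envelope** stands in when no climate record is
at hand: per bin it caps temperature at the point where WBT reaches
31 °C — about the highest wet-bulb temperature occurring in the present
climate — bounded by a hard 55 °C dry-bulb cap, with monotonicity in
humidity enforced against solver round-off.  This reproduces the
qualitative shape of an observed envelope (hot-humid corner excluded,
hot-dry corner admitted, UTCI-invalid conditions partially inside) but
none of its regional or seasonal texture; conclusions about *where*
real conditions fall must use a real envelope file through the same CSV
interface.

## Scenario audit and the synthetic generator

A scenario record is a baseline (T₀, h₀) plus a coupled perturbation
(ΔT in °C, Δq in kg/kg).  Perturbations are specified in *specific*
humidity because that is the variable land-surface interventions move
directly; the perturbed state converts q₀ + Δq back to relative humidity
at the perturbed temperature at fixed pressure.  Supersaturating or
negative-humidity perturbations flag the record; flagged records are
excluded from correlations and conserved in the bookkeeping
(n = used + flagged, verified by test).

The audit computes Δindex per record per index (defined-at-both-ends
only), then Kendall's τ-b and Spearman's ρ between Δq and each Δindex
(scipy implementations, checked in the suite against an O(n²)
concordance count and a rank-then-Pearson construction).  τ-b is the
tie-corrected variant, chosen because modelled deltas routinely tie
after rounding.  A reversal flag is raised when two indices' τ have
opposite signs.

The synthetic generator emulates the *structure* of soil-moisture
modelling experiments — heatwave baselines with anti-correlated
temperature/moisture responses — not any particular dataset: baselines
uniform on T ∈ [30, 42] °C and h ∈ [15, 60] % (hot, dry-to-moderate);
Δq uniform on ±2 g/kg; ΔT = c·Δq + ε with coupling c = −0.7 °C per g/kg
and ε Gaussian with σ = 0.2 °C.  The coupling magnitude is of the order
seen in irrigation/soil-moisture modelling (roughly a degree of cooling
per g/kg of moistening) and the noise keeps the coupling strong but not
deterministic.  Everything derives from one integer seed.  What passing
audits show is that the *sign-reversal phenomenon* (Δq raises WBT and Ts
while lowering UTCI, with HI and AT also negative) is a robust property
of the indices under this perturbation structure; the synthetic τ values
themselves are not estimates of any published experiment's values, which
depend on that experiment's modelled deltas.

## Numerical and interface choices

- Solver tolerances: WBT 10⁻³ °C (documented contract 0.01 °C);
  envelope root-finding 10⁻³ °C; all evaluators deterministic
  (bit-identical outputs for identical states).
- Supersaturation on conversion back from specific humidity raises a
  flagged error rather than clipping; a ≤ 10⁻⁹ overshoot from round-off
  is snapped to 100 %.
- Degenerate inputs: empty grids, empty observation sets, unknown index
  names, sub-minimum scenario counts and non-negative couplings are
  usage errors; unbracketed isopleth levels and humidity-flat indices
  are flagged results, not errors.
- CSV/JSON interfaces use long-format tables with fixed float formatting
  so identical configs reproduce outputs byte-for-byte; every CLI run
  writes a `config_echo.json` sufficient to reproduce it.
- Problem sizes in the shipped checks (isopleth grids of 0.25 °C × 0.5 %,
  audits of 200 records × 10 seeds) were chosen so the full suite runs in
  seconds while keeping isopleth interpolation error an order of
  magnitude below the tolerances asserted.

## Known limitations

- The saturation curve is liquid-water only; below 0 °C the indices are
  evaluated but WBT/θ_E ignore ice-phase effects.
- The pseudoadiabatic WBT definition differs from psychrometer readings
  by up to ~0.5 °C in hot dry air; comparisons with station wet-bulb data
  should expect that offset.
- UTCI is represented by its polynomial approximation (±1–2 K fit error
  against the underlying physiological model, larger near the validity
  edges), not by the model itself.
- The envelope is global and unweighted: one T_max per humidity bin,
  with no notion of location, season or frequency beyond "occurred".
- Synthetic scenarios and envelopes are structural stand-ins; none of
  their outputs quantify any real region, period or dataset.
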