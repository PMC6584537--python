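# Methods

## The model

`ediacaran_o2` is a global biogeochemical box model of the coupled carbon,
oxygen, phosphorus, nitrogen and sulphur cycles in the COPSE family, with an
ocean–sediment strontium-isotope system, configured for the late
Neoproterozoic (no land plants) and driven by two tectonic forcings: the
relative degassing rate D(t) and the relative uplift/erosion rate U(t). Its
purpose is to quantify whether a reconstructed rise in tectonic CO₂
degassing across the Ediacaran Period (635–541 Ma) can raise atmospheric
oxygen, and by how much, given the parameter uncertainty of this class of
model.

Five ocean–atmosphere reservoirs evolve: phosphate P, nitrate N, oxygen O,
carbon A (atmosphere + ocean CO₂/DIC) and sulphate S, plus ocean and
sedimentary-carbonate strontium (OSr, SSr) and four isotope moments
(reservoir mass × composition, carrying δ¹³C, δ³⁴S and the two ⁸⁷Sr/⁸⁶Sr
ratios). The large crustal reservoirs (carbonate C, organic carbon G,
pyrite PYR, gypsum GYP) are frozen at their present relative size: their
fractional change over a ~110 Myr window is negligible, and freezing them
avoids coupling the model to mantle–crust exchange.

The flux laws are the standard COPSE forms. Marine new production is
limited by the scarcer of N and P (Redfield ratios r_C:P = 117,
r_N:P = 16); marine organic carbon burial scales with production squared
and with erosion, mocb = k₂·U·(newp/newp₀)²; carbonate burial closes the
alkalinity budget, mccb = silw + carbw + mpsb − pyrw − pyrdeg; pyrite
burial scales with the sulphate-to-oxygen ratio and relative organic
burial, mpsb = k_mpsb·(s/o)·mocb′, which makes it the dominant oxygen
regulator when the sampled O₂-exponent of oxidative weathering
(oxidw = k₁₇·U·o^a, a ∈ [0, 0.5]) is small. Climate follows RCO₂ = a²
with ΔT = k_c·ln RCO₂ − k_l·t/570 (k_c = sensitivity/ln 2, k_l = 7.4 °C);
weathering carries linearised-Arrhenius temperature factors
exp(E/(R·T₀²)·ΔT) with T₀ = 288 K, runoff factors (1 + 0.038 ΔT)^0.65
(silicates, clamped at 0) and 1 + 0.087 ΔT (carbonates/evaporites), and a
biotic factor that blends vegetated weathering (1 at present) with the
pre-plant rate k15·RCO₂^0.5, k15 = 0.15. The ocean anoxic fraction is
logistic, anox = 1/(1 + exp(−k_anox(k_u·newp′ − o′))) with k_anox = 12,
k_u = 0.5, and gates iron-sorbed P burial and denitrification. A reduced
gas flux (mantle H₂, rgf = k_rgf·D) consumes O₂ mol-for-mol and is paired
with an equal ridge CO₂ input, so the present-day budgets stay linked.

Two printed-but-optional dependences are configurable and off by default:
an O₂ dependence of organic burial, f(O₂) = 2.1276·e^(−0.755·o′)
(normalised to 1 at present O₂), and an anoxia dependence of calcium-bound
P burial (default f(anox) = 1). The direct erosion factor on organic
burial can likewise be disabled (`mocb_uplift_dependence=False`), giving a
purely production-driven burial law; with it disabled, the uplift ramp
becomes a strong net O₂ sink (oxidative weathering still scales with U)
and the simulated Ediacaran O₂ *falls* — the default therefore keeps the
factor, under which erosion is nearly O₂-neutral.

## Present-day closure

The Monte-Carlo machinery samples 17 present-day quantities (fluxes,
activation energies, the oxidative-weathering exponent, climate
sensitivity) from flat distributions over published uncertainty intervals.
Sampled fluxes are not mutually balanced, so a closure construction
derives the remaining constants such that the present-day reference point
— all relative reservoirs 1, all forcings 1, vegetation **on** — is an
exact fixed point:

1. total outgassing splits into carbonate : organic degassing 12 : 1
   (the baseline proportion 1.5×10¹³ : 1.25×10¹²);
2. sampled *total* organic burial splits half marine (k₂), half
   terrestrial (locb₀), the present marine : land proportion of the base
   model; the land-P routing constant k₁₁ follows from locb₀ = CP_land ·
   pland₀;
3. oxidative weathering closes the O₂ budget:
   oxidw₀ = total_ocb + 2(mpsb₀ − pyrw₀ − pyrdeg₀) − ocdeg₀ − rgf₀;
4. silicate weathering closes the carbon budget,
   silw₀ = ccdeg₀ − sfw₀ + (mpsb₀ − pyrw₀ − pyrdeg₀), split
   basalt/granite by the sampled basaltic fraction;
5. the sulphur residual is absorbed into the effective gypsum-burial
   constant (the raw sampled gypsum-burial value is recorded but has no
   dynamical effect);
6. calcium-bound P burial (k₇) and nitrogen fixation (k₃) close the P and
   N budgets.

Draws with a negative derived constant are physically inconsistent and are
rejected and redrawn with the rejection logged (~6% of draws, confined to
the corner of near-maximal organic burial and near-minimal reactive-P
weathering). At the baseline draw the construction reproduces the base
model's own published constants (oxidw₀ = 7.75×10¹², mocb₀ = 4.5×10¹²,
capb₀ ≈ 1.3×10¹⁰ mol/yr), which is the strongest internal check that the
closure reads the uncertainty table correctly.

Ediacaran runs switch vegetation off (pland = locb = 0) and weather at the
pre-plant rate; the thermostat then holds silicate weathering near the
degassing-imposed value at correspondingly higher CO₂ (tens of PAL).

## Forcings

The degassing envelope is a synthetic stand-in for a subduction-zone-length
reconstruction that is not available as numbers: the default window rises
linearly from 1.0–1.2 at 650 Ma to 1.4–1.6 at 541 Ma (half-width 0.1), and
each run draws one value per 10-Myr segment, uniformly within the envelope
at the segment midpoint, held constant within the segment (a step
function; linear blending is available). A user-supplied node table
(CSV: t_Ma, d_min, d_max) replaces the default. **The absolute calibration
of this window is the single largest reproduction uncertainty in the
package**, and the window-sensitive headline numbers should be read with
that in mind.

Uplift ramps linearly from 0.5 at 650 Ma to 2.0 at 541 Ma (held constant
over the 541–540 Ma tail), a magnitude set by the observed rise in
seawater ⁸⁷Sr/⁸⁶Sr; u_start = u_end gives the constant-uplift variant.
Land-area and carbonate forcings stay at 1; vegetation is 0 throughout.

Runs span 650→540 Ma so that both averaging windows used in the analysis
(640–620 and 560–540 Ma) lie inside the trajectory.

## Strontium system

Ocean Sr inputs (mantle ∝ D; basalt/granite weathering ∝ the carbon-cycle
fluxes; carbonate-sediment weathering ∝ carbw·SSr′) balance outputs
(carbonate burial ∝ mccb·OSr′; seafloor weathering ∝ sfw·OSr′) at the
present day, with the removal split in the present carbonate-burial :
seafloor-weathering proportion. There is no Sr isotope fractionation; the
⁸⁷Sr/⁸⁶Sr contrast between end members comes from ⁸⁷Rb decay
(λ = 1.42×10⁻¹¹ yr⁻¹): each rock type's Rb/Sr is calibrated so its
present ratio (granite 0.715, basalt 0.705, mantle 0.703) is reached after
4.5 Gyr from the common initial ratio 0.69898, and end members are
evaluated at the geological age being simulated. The carbonate-sediment
reservoir additionally accumulates radiogenic ⁸⁷Sr during a transient run,
with its Rb/Sr calibrated to the average crustal ratio 0.73; this in-run
ingrowth clock is frozen during spin-up and starts at the transient's
first step. The sediment reservoir is *not* forced to present-day steady
state (only the ocean is); it relaxes to its own equilibrium during
spin-up.

## Numerics

The state is integrated in transformed coordinates — log relative masses
(so positivity is structural) and moments normalised by present reservoir
size — with an adaptive stiff solver (LSODA, rtol 10⁻⁶, atol 10⁻⁹ in the
transformed coordinates; a BDF retry on rare hard failures at forcing
steps), restarting at each 10-Myr degassing step, with output on a uniform
1-Myr grid. Negative carbonate burial under extreme draws is clamped at
zero and flagged; a clamp persisting beyond 1 Myr invalidates the run for
ensemble statistics.

Steady states integrate the autonomous system (forcings, solar term, Sr
end members frozen at the stated epoch) in expanding chunks up to 10 Gyr,
with a guarded Newton polish of the fixed point after each chunk; the
polish must stay within the basin (bounded move in log coordinates) and
strictly reduce the residual. Convergence means a maximum relative
derivative below 10⁻¹⁰ yr⁻¹ and is reported honestly — the weak-feedback
corner (oxidative exponent ≈ 0) is exactly where the polish matters.
Multi-start probing found no second attractor at the draws examined.

## Monte-Carlo design

Per-run substreams are keyed (master seed, run index) via seed-sequence
spawning, so results are bit-identical under any worker count and adding
runs never perturbs existing ones. Each member: sample-and-close a
parameter draw, draw a degassing path, spin up to steady state under its
own 650-Ma forcing (the experiment does not prescribe an initialisation; a
self-consistent steady start avoids arbitrary transients), then integrate
the transient. Runs failing the solver or the clamp rule are excluded and
counted; the ensemble errors out if more than 10% are invalid. Band
statistics are per-time mean ± 0.5 and ± 1 sample standard deviations over
valid runs; the O₂-change statistic is the per-run fractional change of
window-mean O₂ (640–620 vs 560–540 Ma), reported as a percentage of the
early value.

The full experiment is 10,000 runs; the package's documented reduced mode
(300 runs, used by the analysis drivers and the acceptance script) gives
standard errors on ensemble means of ~6%/√300 of the across-run spread,
ample for the headline window statistics.

## Trend regression

Ordinary least squares of proxy value on age, on the raw record and on
records binned into fixed-width (5/10 Myr) groups anchored at the old end,
with unweighted bin means and no outlier rejection. The reported slope is
per Myr toward the present (positive = rising toward the present); the
p-value is the two-sided t-test on the slope. The synthetic proxy
generator draws ages uniformly over a span and adds a linear trend, boxcar
excursions and Gaussian noise, recording its ground truth so recovery is
testable. What the generator does not emulate: age-error structure,
diagenetic covariance, uneven stratigraphic sampling density — so passing
recovery tests demonstrate the regression machinery, not robustness to
those features of real compilations.

## Known limitations

- The degassing window is an explicit approximation (see above); the
  window-sensitive ensemble quantities (absolute O₂ levels, the size and
  tightness of the O₂ rise) inherit its uncertainty and sit above the
  published central values under the default window.
- Under the printed flux laws the steady-state O₂ response to uplift is
  near-neutral but not monotonically decreasing: at low uplift the
  anoxia–phosphorus recycling feedback can invert the direction.
- Unprinted constants are adopted from the base model's published values
  and are version-dependent; all are exposed in configuration.
- The model is a single global box: it says nothing about spatially
  resolved ocean redox, and the vegetation-off weathering mode uses one
  (configurable) pre-plant factor for all lithologies.
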