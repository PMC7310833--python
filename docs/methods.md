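# Methods

This note records the models, conventions, numerical choices and known
limitations behind `thermokin`. Anything that could be done more than one
defensible way is stated here with the rationale.

## 1. Michaelis–Menten estimation (`mm_kinetics`)

**Model.** v = V<sub>max</sub>·S/(K<sub>m</sub>+S), fitted by nonlinear
least squares (`scipy.optimize.curve_fit`, trust-region reflective with
non-negativity bounds). No Lineweaver–Burk or other linearisation is
used: the double-reciprocal transform distorts the error structure and
over-weights low-substrate points.

**Initialisation.** V<sub>max,0</sub> is the maximum observed rate;
K<sub>m,0</sub> is the substrate concentration linearly interpolated at
half of V<sub>max,0</sub> (falling back to the median concentration if
the interpolation is non-positive). Convergence tolerances are
xtol = ftol = gtol = 10⁻¹², so on noiseless hyperbolic data the fit
recovers the generating parameters to relative error ≤ 10⁻⁶ over
K<sub>m</sub> ∈ [1, 100] mM, V<sub>max</sub> ∈ [0.1, 10] U/mg (property-
tested). Tests also cross-check the solver against an independent
brute-force oracle: a one-dimensional K<sub>m</sub> scan with
V<sub>max</sub> profiled analytically (for fixed K<sub>m</sub> the model
is linear in V<sub>max</sub>).

**Replicates.** By default all replicate points enter the fit, which
implicitly weights concentrations by their replication; `use_means=True`
fits per-concentration means instead. At least three distinct
concentrations are required (two parameters plus one degree of freedom).

**Turnover number.** k<sub>cat</sub> = V<sub>max</sub> · 10⁻⁶ ·
M<sub>w</sub> / 60, with V<sub>max</sub> in µmol·min⁻¹·mg⁻¹ and
M<sub>w</sub> in g/mol. This is the fixed convention of the package: the
specific activity's mass of enzyme is converted to moles through the
molar mass, micromoles of product to moles, and minutes to seconds. Some
published k<sub>cat</sub> values for mass-normalised activities are not
derivable this way (the bundled reference's printed k<sub>cat</sub> is
one; it is flagged, not reproduced — see §6). Catalytic efficiency is
k<sub>cat</sub>/K<sub>m</sub> in M⁻¹·s⁻¹ (K<sub>m</sub> mM → M).

**Binding free energies.** With R·T in kJ/mol and K<sub>m</sub> in molar:

- ΔG<sub>ES</sub> = −R·T·ln(1/K<sub>m</sub>) (binding free energy of the
  ES complex, association constant 1/K<sub>m</sub>);
- ΔG<sub>E-T</sub> = −R·T·ln(k<sub>cat</sub>/K<sub>m</sub>) in `strict`
  mode. `compat` mode returns +R·T·ln(k<sub>cat</sub>/K<sub>m</sub>),
  the sign convention under which some published tables print a negative
  value whenever the efficiency is below 1 M⁻¹·s⁻¹. The modes are exact
  negations; the property suite asserts this.
- K<sub>a</sub> = 1/K<sub>m</sub> is reported in mM⁻¹.

An `efficiency_M_s` override lets the caller evaluate ΔG<sub>E-T</sub>
from a printed efficiency that is not internally consistent with the
printed k<sub>cat</sub> and K<sub>m</sub>.

## 2. Thermal inactivation (`inactivation`)

**Model.** ln([A]<sub>t</sub>/[A]<sub>0</sub>) = −k<sub>in</sub>·t.
Series are constructed from residual-activity *fractions* with t = 0 and
fraction(0) = 1 enforced; non-positive fractions (complete inactivation
within instrument resolution) are dropped with a warning because their
logarithm is undefined.

**Fit.** Default is through-origin ordinary least squares — the fraction
at t = 0 is exactly 1 by construction, so the intercept is a known zero:
slope = Σt·y / Σt², with an uncentred r². `intercept_mode="free"`
provides the two-parameter diagnostic fit (a non-zero intercept indicates
a lag or burst phase violating first-order kinetics). A series with no
measurable decay yields k<sub>in</sub> = 0, t<sub>1/2</sub> = NaN and a
`DegenerateFitWarning` rather than an exception.

**Derived metrics.** t<sub>1/2</sub> = ln 2 / k<sub>in</sub>. The
decimal-reduction time has two conventions:

- `standard`: D = ln 10 / k<sub>in</sub> (time for 90% activity loss,
  the food-science definition);
- `compat`: D = (R·T in kJ/mol) / k<sub>in</sub>, which reproduces the
  bundled reference table's printed D column. It is not a time for any
  fixed fractional loss and is kept only for table compatibility; the
  mode is recorded in every fit result.

`inactivation_table` fits one series per temperature, rejects duplicate
temperatures, and returns fits sorted by temperature.

## 3. Thermodynamics (`thermodynamics`)

**Arrhenius.** E<sub>a</sub> = −slope(ln k vs 1/T)·R by ordinary least
squares (`numpy.polyfit`); two-point inputs reduce to the closed form.

**Eyring.** ΔG<sup>#</sup> = −R·T·ln(k·h/(k<sub>B</sub>·T)). The rate
constant's unit tag (`"1/s"` or `"1/min"`) is a **mandatory argument and
is used as-is** — there is no silent conversion. Converting min⁻¹ to s⁻¹
shifts ΔG<sup>#</sup> by exactly R·T·ln 60 (≈ 11.3 kJ/mol at 60 °C), so
the choice must be the caller's, and it is recorded in the output. The
bundled reference tables use min⁻¹.

**Activation chain.** ΔH<sup>#</sup> = E<sub>a</sub> − R·T;
ΔS<sup>#</sup> = 1000·(ΔH<sup>#</sup> − ΔG<sup>#</sup>)/T in J·mol⁻¹·K⁻¹
(signed; negative for these fits). Where a source table prints the
magnitude |ΔS<sup>#</sup>|, comparison is against the magnitude and the
sign convention is stated in the output tags. The Gibbs–Helmholtz
identity ΔG = ΔH − T·ΔS/1000 holds on every generated table row to
1 × 10⁻⁹ kJ/mol (property-tested).

**Constants.** `CODATA` (default) uses full-precision k<sub>B</sub>, h,
R. `COMPAT` uses the three-significant-figure values found in printed
tables (k<sub>B</sub> = 1.38 × 10⁻²³, h = 6.63 × 10⁻³⁴, R = 8.314).
The difference moves ΔG<sup>#</sup> by a few parts in 10⁴ — enough to
matter when matching a table printed to two decimals.

## 4. Synthetic data (`synthetic_data`)

The generator's defaults **are** the reference study conditions; they are
not tuning knobs:

| Parameter | Default | Rationale |
| --- | --- | --- |
| K<sub>m</sub>, V<sub>max</sub> | 13.72 mM, 2.657 U/mg | reference enzyme |
| substrate grid | 10–70 mM, 7 points | saturation design spanning ~0.7–5 × K<sub>m</sub> |
| inactivation E<sub>a</sub>, k<sub>ref</sub>, T<sub>ref</sub> | 50.31 kJ/mol, 2.10 × 10⁻³ min⁻¹, 333.15 K | reference Arrhenius law anchored at the 60 °C optimum |
| temperatures | 60–100 °C | reference stability panel |
| time grid | 0–120 min, step 10 | reference incubation design |
| replicates | 3 | assays performed in triplicate |
| noise | lognormal, σ = 0.02 | multiplicative 2% assay error; activities stay positive |

Noise is multiplicative lognormal because activity assays have
approximately constant *relative* error and cannot go negative. The t = 0
point of each time course is noise-free (it defines the normalisation).
Sub-streams of `numpy.random.default_rng([seed, stream])` keep the MM,
inactivation and effector draws independent, so the same seed gives
byte-identical datasets and changing one block does not perturb another.

What the generator emulates: triplicate initial-rate and residual-
activity measurements under the reference design, with truth recorded in
a `TruthBundle`. What it does not emulate: pipetting bias, enzyme-batch
variation, substrate depletion within the initial-rate window, or
deviations from strict first-order decay.

Recovery performance at the defaults (asserted in tests): median
K<sub>m</sub> error < 5% over 200 seeds; noiseless E<sub>a</sub> recovery
exact to 10⁻⁹ relative; E<sub>a</sub> within 2% of truth in ≥ 90 of 100
seeds (99/100 at base seed 1).

## 5. Assay core conventions (`assay_core`)

- Replicates aggregate as arithmetic mean; spread is the sample SD
  (n − 1). Relative activity scales the test SD by the same factor as
  the mean, treating the control as a fixed reference; a non-positive
  control raises `InvalidControlError`.
- Purification: the first step is the reference (yield 100%, fold 1);
  full-precision values are returned and rounding is a separate display
  step (`format_purification_table`), so print-precision comparisons are
  explicit.
- Substrate specificity: best substrate = 100%, descending order, ties
  broken alphabetically. Profile optimum: ties resolve to the lower grid
  value.
- Effector records carry a closed class set (metal_ion, organic_solvent,
  inhibitor, surfactant) to catch typos at construction time.

## 6. Reference fixture and flagged cells (`cli_report`)

The package bundles the full reference characterization
(`data/reference_protease.json`) and `thermokin reproduce` recomputes
every derivable cell from its upstream inputs. Cells that cannot be
reproduced from the other values in the same table are **flagged** with
their deviation, never adjusted:

- t<sub>1/2</sub> at 100 °C: printed 22.27 vs ln 2/k<sub>in</sub> = 22.22 min;
- ΔH<sup>#</sup> at 70 °C: printed 47.54 duplicates the 60 °C cell;
  E<sub>a</sub> − R·T at 343.15 K = 47.46;
- the table's E<sub>a</sub> (50.31): an Arrhenius fit of the table's own
  k<sub>in</sub> column gives 63.12 kJ/mol;
- k<sub>cat</sub> and efficiency: printed 3.143 × 10⁻³ s⁻¹ / 0.381 M⁻¹s⁻¹
  are not derivable from V<sub>max</sub> = 2.657 U/mg and M<sub>w</sub> =
  18 kDa under any standard unit convention (§1 gives 7.97 × 10⁻⁴ / 0.229);
- ΔG<sub>ES</sub>: printed +0.19 vs −R·T·ln(1/K<sub>m</sub>) = −11.88 kJ/mol;
- crude-extract specific activity (printed 0.28, computed 0.287 → 0.29),
  thermal-shock yield (73.1 vs 73.0) and two fold values — one-decimal
  print-precision mismatches;
- purification fold 62.3/45.4 vs computed 61.8/44.9.

## 7. Numerical choices and degenerate inputs

- Tolerances: curve_fit xtol/ftol/gtol 10⁻¹²; Gibbs–Helmholtz identity
  asserted to 10⁻⁹ kJ/mol; grid-search oracle step 10⁻³ mM.
- Tie-breaks: substrate ranking alphabetical within equal percentages;
  profile optimum takes the lower grid value.
- Degenerate inputs: < 3 distinct substrate concentrations, duplicate
  panel temperatures, non-increasing time grids, non-positive controls
  and empty tables raise `ValueError`; flat decay warns and returns
  k<sub>in</sub> = 0; non-positive fractions are dropped with a warning.
- JSON reports are serialised with sorted keys so identical analyses are
  byte-identical.

## 8. Open design decisions

- **k<sub>cat</sub> mass basis** (§1): fixed to the molar-mass
  conversion; alternative active-site-titration bases are out of scope.
- **`compat` D value** (§2): retained purely for table compatibility.
- **min⁻¹ in Eyring** (§3): unit tags are caller-supplied and recorded;
  the package never guesses.
- **Signed entropy** (§3): ΔS<sup>#</sup> is reported signed; magnitude
  comparison is an explicit display choice.
- **Triplicates** (§4): the generator default matches the triplicate
  study design; single-replicate simulation is available but
  E<sub>a</sub> recovery degrades (≈ 77/100 seeds within 2% instead of
  ≥ 90/100).

## 9. Known limitations

- Only the irreversible first-order inactivation model is implemented;
  biphasic or Lumry–Eyring decay must be diagnosed via the free-intercept
  fit and handled upstream.
- No inhibition models (competitive/uncompetitive/mixed) and no substrate
  inhibition in the MM module.
- Parameter uncertainties are asymptotic (covariance-based); no bootstrap
  or profile-likelihood intervals.
- Problem sizes throughout (7-point saturation curves, 13-point time
  courses, 5 temperatures, 100–200 seed recovery experiments) are the
  package's chosen defaults for its test and acceptance suites; all are
  overridable via the pydantic configs.
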