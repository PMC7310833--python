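# thermokin

Enzyme kinetics and thermostability analysis for thermostable proteases
(and hydrolases generally), built around the characterization workflow of
a recombinant 18 kDa thermostable cysteine protease: substrate-saturation
kinetics, thermal-inactivation kinetics, and the activation/inactivation
thermodynamics derived from them.

## Who this is for

Enzymologists and protein engineers who have:

- initial-rate measurements over a substrate concentration series,
- residual-activity time courses at several incubation temperatures,
- effector panels (metal ions, solvents, surfactants, inhibitors),
  purification tables and temperature/pH activity profiles,

and want the standard derived quantities — K<sub>m</sub>, V<sub>max</sub>,
k<sub>cat</sub>, k<sub>cat</sub>/K<sub>m</sub>, k<sub>in</sub>,
t<sub>1/2</sub>, D values, E<sub>a</sub>, ΔH<sup>#</sup>, ΔG<sup>#</sup>,
ΔS<sup>#</sup> — computed with explicit, testable conventions instead of
spreadsheet folklore.

## Models

**Michaelis–Menten** (nonlinear least squares, no linearisation):

    v = Vmax · [S] / (Km + [S])

with k<sub>cat</sub> = V<sub>max</sub> · 10⁻⁶ · M<sub>w</sub> / 60 (V<sub>max</sub>
in µmol·min⁻¹·mg⁻¹, M<sub>w</sub> in g/mol) and catalytic efficiency
k<sub>cat</sub>/K<sub>m</sub> in M⁻¹·s⁻¹.

**First-order thermal inactivation** (through-origin log-linear fit):

    ln([A]_t / [A]_0) = −k_in · t,   t_1/2 = ln 2 / k_in,   D = ln 10 / k_in

**Arrhenius / Eyring / Gibbs–Helmholtz:**

    ln k = ln A − Ea/(R·T)
    ΔG# = −R·T · ln(k·h / (kB·T))
    ΔH# = Ea − R·T
    ΔS# = (ΔH# − ΔG#) / T
    ΔG  = ΔH − T·ΔS

**Binding free energies:**

    ΔG_ES  = −R·T · ln(1/Km)          (Km in molar)
    ΔG_E-T = −R·T · ln(kcat/Km)       ("strict"; "compat" mode uses the opposite sign)

Every convention choice (rate units entering Eyring, the D-value variant,
signed vs. magnitude entropy, the mass basis of k<sub>cat</sub>) is an
explicit argument with the rationale documented in
[docs/methods.md](docs/methods.md).

## Modules

| Module | Purpose |
| --- | --- |
| `thermokin.assay_core` | activity measurements, effector panels, purification tables, profiles, CSV readers |
| `thermokin.mm_kinetics` | Michaelis–Menten fitting, k<sub>cat</sub>, efficiency, binding free energies |
| `thermokin.inactivation` | first-order inactivation fits, t<sub>1/2</sub>, D values |
| `thermokin.thermodynamics` | Arrhenius, Eyring, activation/inactivation thermodynamic tables |
| `thermokin.synthetic_data` | seeded generator whose defaults are the reference study conditions |
| `thermokin.cli_report` | `thermokin` CLI: `simulate`, `analyze`, `reproduce` |

## Worked example

Simulate a full characterization at the reference conditions (seed 7),
fit both models, and derive the thermodynamic table:

```python
from thermokin.synthetic_data import GeneratorConfig, simulate_mm, simulate_inactivation
from thermokin.mm_kinetics import fit_mm
from thermokin.inactivation import inactivation_table
from thermokin.thermodynamics import arrhenius_fit, inactivation_thermo_table
from thermokin.constants import COMPAT

cfg = GeneratorConfig(seed=7)
curve, truth = simulate_mm(cfg)
res = fit_mm(curve, mw_g_mol=18000)
print(f"Km   = {res.Km:.2f} mM   (true {truth.config.mm.Km})")
print(f"Vmax = {res.Vmax:.3f} U/mg (true {truth.config.mm.Vmax})")
print(f"kcat = {res.kcat:.3e} s^-1,  kcat/Km = {res.efficiency:.3f} M^-1 s^-1")

series, truth = simulate_inactivation(cfg)
fits = inactivation_table(series)
arr = arrhenius_fit([f.temperature for f in fits], [f.kin for f in fits], "1/min", COMPAT)
print(f"\nEa(inactivation) = {arr.Ea:.2f} kJ/mol (true {truth.config.inactivation.Ea})")
table = inactivation_thermo_table(fits, Ea_in=arr.Ea, constants=COMPAT)
print(table.round(3).to_string(index=False))
```

Output:

```
Km   = 13.68 mM   (true 13.72)
Vmax = 2.624 U/mg (true 2.657)
kcat = 7.872e-04 s^-1,  kcat/Km = 0.058 M^-1 s^-1

Ea(inactivation) = 50.73 kJ/mol (true 50.31)
 temperature_C  kin_per_min  t_half_min  d_value_min   d_mode  Ea_kJ_mol  dH_kJ_mol  dG_kJ_mol  dS_J_mol_K
            60        0.002     334.538     1111.312 standard     50.728     47.958     99.012    -153.246
            70        0.004     197.124      654.831 standard     50.728     47.875    100.559    -153.532
            80        0.006     116.545      387.154 standard     50.728     47.792    102.031    -153.587
            90        0.009      73.507      244.184 standard     50.728     47.708    103.613    -153.943
           100        0.015      47.167      156.684 standard     50.728     47.625    105.174    -154.223
```

The same workflow is available from the command line:

```bash
thermokin simulate --seed 7 --out data/          # write CSVs + truth.json
thermokin analyze data/*.csv --mode compat --mw 18000 --out report.json
thermokin reproduce                              # recompute the bundled reference tables
```

`thermokin reproduce` recomputes every derivable cell of the bundled
reference characterization from its upstream inputs and prints a
computed-vs-printed comparison. A small set of cells is *flagged*: they
cannot be recovered from the other values in the same table (for example
the inactivation-table activation energy, which differs from the value an
Arrhenius fit of the table's own rate constants produces, and a ΔH<sup>#</sup>
entry that duplicates the row above it). Flagged cells are reported with
their deviations, never silently adjusted; see
[docs/methods.md](docs/methods.md) for the full list.

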