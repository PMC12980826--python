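# aavsorb

Recombinant adeno-associated virus (rAAV) vectors are lost during
manufacturing and fill–finish because the ~26 nm capsids adsorb
nonspecifically onto container and processing surfaces. `aavsorb`
implements a predictive pipeline for that loss: it derives
physicochemical descriptors of both sides of the interface — the capsid
(outer-surface solvent-accessible surface area split by residue
chemistry, zeta potential, net charge) and the solid surface (water
contact angle, sign-split zeta potential) — and links them to the
measured adsorption ratio with a multiple linear regression.

The core model is

```
A = β0 + β1·θ + β2·ζpos + β3·ζneg + β4·S_hydrophobic + β5·S_hydrophilic
```

where `A` is the adsorption ratio (% titer loss after incubation,
clamped at 0), `θ` the surface contact angle (deg), `ζpos`/`ζneg` the
positive and negative components of the surface zeta potential (mV),
and `S_hydrophobic`/`S_hydrophilic` the outer side-chain SASA (Å²) of
hydrophobic vs acidic+basic residues on the capsid exterior. Splitting
ζ by sign lets electrostatic attraction to positive surfaces and the
residual (charge-patch mediated) adsorption to negative surfaces carry
separate coefficients; the nested variants S1 `{θ, ζ}`, S2
`{θ, ζpos, ζneg}` and final (adds the SASA terms) expose how much each
mechanism explains.

## What's in the box

| module | role |
| --- | --- |
| `aavsorb.capsid_surface` | PDB parsing with REMARK 350 assembly expansion, Shrake–Rupley SASA (golden-spiral quadrature), outer-shell (>105 Å from the capsid center) side-chain sums by residue category |
| `aavsorb.colloid_props` | Smoluchowski mobility→zeta conversion, Einstein-relation net charge, surface condition tables |
| `aavsorb.adsorption_stats` | clamped adsorption ratios from titer pairs, triplicate summaries, pooled-variance Student's t-tests with star annotations |
| `aavsorb.regression_model` | sign-split design construction, nested OLS fits with standardized coefficients, prediction and validation R² |
| `aavsorb.synthetic_data` | study-shaped simulated adsorption panels with known coefficients, and toy capsids with analytic SASA ground truth |
| `aavsorb.cli_io` / `aavsorb.cli` | YAML-configured end-to-end pipeline with a JSON run manifest; `aavsorb` CLI (`sasa`, `simulate`, `fit`, `predict`, `run`) |

## Worked example

Run the pipeline end to end on a simulated panel with the study layout
(4 serotypes × 3 surfaces × 2 ionic strengths, triplicates):

```sh
$ aavsorb run --seed 1 --out runs/demo
variant S1: R² = 0.617 (n = 24)
variant S2: R² = 0.973 (n = 24)
variant final: R² = 0.999 (n = 24)
```

The R² progression is the point of the model: contact angle plus raw
zeta (S1) explains adsorption poorly, splitting the zeta potential by
sign (S2) captures the asymmetric electrostatics, and adding the capsid
SASA descriptors (final) accounts for the serotype differences.
`runs/demo/` contains the generated tables, per-variant coefficient
reports, standardized coefficients, saved fits and `manifest.json`
(config echo, input checksums, R² per variant). The final-variant
coefficient report starts:

```
variable,coefficient,se,t,p
intercept,7.0304,4.5050,1.5606,0.1360
theta_deg,0.3271,0.0075,43.894,9.29e-20
zeta_pos_mV,2.4611,0.0203,121.24,1.14e-27
```

i.e. each degree of contact angle adds ~0.33 percentage points of
adsorption and each mV of positive surface charge ~2.5 points, close to
the generating coefficients of the simulation. Library use mirrors the
CLI:

```python
from aavsorb.synthetic_data import PanelSpec, simulate_panel
from aavsorb.regression_model import fit_model, predict

panel = simulate_panel(PanelSpec(seed=1))
fit = fit_model(panel.merged(), variant="final")
print(fit.r_squared, fit.standardized_coefficients)
pred = predict(fit, panel.merged())
```

To compute descriptors for a real capsid, point `aavsorb sasa` at a PDB
entry with biological-assembly transforms (e.g. 1lp3 for AAV2):

```sh
aavsorb sasa --pdb 1lp3.pdb --serotype AAV2 --out aav2_descriptor.csv
```

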