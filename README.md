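# plaquefem

Parametric plane-stress finite-element analysis of calcified
atherosclerotic plaque cross-sections.

Rupture of an atherosclerotic plaque — the thin fibrous cap tearing over
its lipid core — is a mechanical event: histology associates it with caps
thinner than 65 μm, and biomechanical studies with peak cap stresses above
~300 kPa. Micro-calcifications clustered inside the lipid pool
("calcification agglomerates") change the picture: a stiff agglomerate
close behind the cap shields it, while a wide lipid gap between cap and
agglomerate leaves the cap nearly as loaded as in a non-calcified plaque.
This package is for biomechanics researchers who want a transparent,
fully scripted 2D model of that trade-off.

## What it computes

A parameterized half cross-section of a stenosed artery — arterial wall,
fibrous plaque, eccentric lumen, 140° lipid crescent at cap thickness
`d_fc`, optional calcification agglomerate at gap `d_cg` — is meshed with
quadratic triangles conforming to every tissue interface and solved in
linear plane stress under luminal pressure `P` (14.6 kPa by default) with
symmetry conditions. For each model the package reports

* `σ_cr` — the critical stress: peak maximum principal stress on the
  fibrous cap,
* `D_max` — peak cap displacement magnitude,
* `σ_max/P` — pressure-normalized peak circumferential stress,

and sweeps them over cap thickness, calcification gap, and composite
elasticity (`E_lp`, `E_cag`); the agglomerate's default stiffness comes
from a rule of mixtures over its constituents,
`E_i(cag) = α E_i(ft) + β E_i(lp) + γ E_i(Ca)` with α, β, γ = 5%, 20%,
75%. Rupture thresholds are located by interpolating the σ_cr = 300 kPa
crossing along a sweep axis. A quasi-static pulsatile envelope rescales
any solution along a pressure waveform. See `docs/methods.md` for the
model, its assumptions, and the verification suite (Lamé benchmark,
frame objectivity, full/half equivalence, grid independence).

## Worked example

The thin-cap reference model: 70% stenosis, 0.05 mm cap, soft lipid
(E_lp = 1 kPa), no calcification.

```python
import plaquefem as pf

res = pf.solve_model(
    pf.PlaqueGeometrySpec(stenosis=0.70, d_fc=0.05),
    level="medium", E_lp=1.0,
)
v = pf.classify(res.summary, res.spec)
print(f"sigma_cr = {res.summary.sigma_cr:.1f} kPa")
print(f"D_max    = {res.summary.D_max:.3f} mm")
print(f"verdict  = {v.verdict} (thin cap: {v.thin_cap})")
```

prints

```
sigma_cr = 349.8 kPa
D_max    = 0.380 mm
verdict  = rupture-risk (thin cap: True)
```

The cap stress exceeds the 300 kPa rupture threshold and the cap is
thinner than 65 μm, so the model is flagged vulnerable on both criteria;
the cap deflects 0.38 mm into the nearly fluid lipid pool. Thickening
the cap to 0.48 mm (90% stenosis in the constant-lipid family) drops
σ_cr to ~27 kPa — stable. Adding an agglomerate behind the cap lowers
σ_cr monotonically as the gap `d_cg` shrinks:

```sh
plaquefem thresholds --level coarse --out out/
# d_cg* = 0.090 mm, D_max* = 0.306 mm
```

i.e. on the coarse grid the cap crosses the rupture threshold once the
calcification gap exceeds ~0.09 mm. The same CLI exposes `geometry`,
`solve`, `sweep`, `validate` and `report` subcommands; outputs are CSV
sweep tables, JSON summaries/thresholds and VTU fields for ParaView.

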