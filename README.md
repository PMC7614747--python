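# neodose

RF dosimetry and thermal-safety analysis for **neonatal MRI at 7 T with an
adult head coil**: synthetic neonate voxel phantoms, age-adjusted tissue
dielectric properties, region- and 10 g mass-averaged SAR with the
normalization conventions scanners actually enforce, an explicit
finite-difference Pennes bioheat solver with a dynamic blood-pool core
temperature and thermal insulation, and IEC compliance evaluation with
heat-transfer-coefficient sensitivity sweeps.

## The problem

Neonates imaged at ultrahigh field sit almost entirely inside a head
transmit coil, so the coil behaves more like a body coil for them: both
local and systemic heating matter.  Their tissues hold more water than
adult tissues (higher permittivity and conductivity), their thermoregulation
is underdeveloped, and a naked neonate in a 22 °C scanner room becomes
hypothermic — in practice they are scanned wrapped in insulation.  This
package provides the quantitative machinery to ask: *at what drive power do
IEC SAR limits bind, and what do core and local temperatures do during an
hour of exposure at that power?*

## What it computes

**SAR.** With RMS field convention, pointwise `SAR = σ|E|²/ρ` (W/kg).
Region averages are mass-weighted; the peak spatial 10 g SAR (psSAR10g)
grows a cube around every tissue voxel until exactly 10 g of tissue is
enclosed (fractionally weighted outer shell, IEC 62704-1 style) and takes
the maximum.  SAR is reported per input power, per net-forward power
(forward − reflected), per absorbed power, and per mean |B1+|² in a central
axial slice — the four references used by different exposure controls.

**Temperature.** The Pennes bioheat equation per voxel,

    ρc ∂T/∂t = ∇·(k∇T) + ρ·SAR + ρ·q_met + W_b·c_b·(T_blood − T),

solved with an explicit scheme: harmonic-mean face conductances, a Robin
convective boundary `h(T − T_ambient)` on every exterior face, an optional
wool blanket shell that leaves the face uncovered, and a *variable* blood
pool: a lumped 324 mL compartment (typical for a 3.6 kg term neonate) whose
temperature follows the net tissue–blood heat exchange — the mechanism that
makes neonatal core temperature mobile where an adult's is not.

**Compliance.** Operative limits: head-average SAR 3.2 W/kg, psSAR10g
10 W/kg, core-temperature rise 0.5 °C, absolute temperature 39 °C.
`power_for_limit` returns the largest compliant drive power and the binding
limit; `check_thermal` locates limit-crossing times; `h_sensitivity` sweeps
the surface heat-transfer coefficient (±10 %, ±20 %).

Full-wave electromagnetic simulation of the coil is **out of scope**;
exposure fields come from a parametric head-coil surrogate, from HDF5
imports, or — for the published worked examples — from a packaged fixture
of per-model EM summary values.

## Worked example

The derived compliance arithmetic from the packaged EM summary fixture:

```bash
$ neodose reproduce-paper-arithmetic
allowed_power_neonate_W        8.000
allowed_power_adult_W          21.333
binding_limit_neonate          head_avg
binding_limit_adult            head_avg
psSAR10g_at_head_limit_W_kg    8.840
whole_body_at_head_limit_W_kg  1.312
head_ratio_absorbed            3.977
ps_ratio_absorbed              3.646
head_ratio_net_forward         2.984
ps_ratio_net_forward           2.736
head_ratio_b1sq                2.014
ps_ratio_b1sq                  1.873
b1_reduction_factor            1.369
```

Reading: for the term neonate with age-adjusted dielectric properties the
head-average limit binds at 8 W of input power (21.3 W for the adult); at
that operating point the local 10 g peak is 8.8 W/kg (close to its own
10 W/kg limit) and the whole-body average is 1.3 W/kg — systemic exposure
an adult head scan never approaches.  Per unit of achieved B1+², the
neonate absorbs about twice the adult dose, so the usable RMS B1+ should be
derated by ≈ √2.

The same operations run on the synthetic phantom:

```python
import neodose as nd

model = nd.generate_phantom(nd.default_neonate_spec(seed=1))   # 3.503 kg, head 1029 mL
table = nd.apply_age_scaling(nd.load_adult_table(), nd.load_neonate_scaling())
field = nd.surrogate_field(model, table, kind="radial_gradient")
res   = nd.compute_sar(field, model, table)
res.normalizations["input_power"]
# {'head_avg': 0.322, 'whole_body_avg': 0.168, 'psSAR10g': 1.132}   (W/kg/W)
```

The 10 g peak lands in the hand resting near the face — small, air-backed
anatomy concentrates the average.  `neodose run --config pipeline.yaml
--out run/` chains phantom → SAR → allowed power → equilibration → 60 min
exposure → compliance report.

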