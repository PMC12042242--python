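# mdtsim

Simulation of **magnetic drug targeting (MDT) in the central airways with a
bulk superconducting magnet**.

Primary bronchus tumors are hard to dose selectively by inhaled
chemotherapy: most aerosol exits the airways or lands far from the lesion.
If the drug is bound to paramagnetic carrier particles, a strong external
magnet can pull the aerosol onto the tumor. Trapped-field bulk
high-temperature superconductors reach several tesla at their surface — an
order of magnitude above permanent magnets — so they could steer particles
from *outside* the body. `mdtsim` models that system end to end and asks the
quantitative question: **what fraction of inhaled particles deposits on the
tumor surface (the particle deposition efficiency, PDE), and how does it
depend on magnet, particle, airway and tumor parameters?**

## Model

* **Magnet** — a cylindrical bulk superconductor (radius *a*, thickness *t*)
  in the fully magnetized Bean critical state: azimuthal current density
  *J*c everywhere. The trapped field at the top-surface center is
  *B*_T = *k* μ₀ *J*c *a* with *k* = *t*/(2*a*)·asinh(*a*/*t*); the full 3-D
  field is the Biot–Savart superposition of circular loops (complete
  elliptic integrals). *J*c is calibrated so the simulated peak surface
  field matches a measured/published *B*_T; a Kim model
  *J*c(B) = *J*c0·B₀/(B₀+|B|) is available for sensitivity studies.
* **Airway** — the symmetric Weibel tree, generations G0–G3
  (120/9, 47.6/6.1, 19/4.15, 7.6/2.8 mm length/radius), planar, with a
  bronchial wall tumor modeled as a spherical cap of radius
  *r* = (*r*/*R*_G1)·*R*_G1 growing from the epithelium into the lumen.
* **Airflow** — steady laminar inspiration (default 15 L/min, inlet
  Re ≈ 1.2·10³) via a Hagen–Poiseuille resistance network with parabolic
  branch profiles, carinal skew, junction funneling, and a
  potential-flow-plus-separation closure around the tumor cap.
* **Particles** — Lagrangian tracking of paramagnetic drug carriers
  (default 4 µm, 5230 kg/m³, μ_r,p = 9) under Schiller–Naumann drag and the
  magnetophoretic force
  F_m = (π/4) d_p³ μ₀ (μ_r,p−1)/(μ_r,p+2) ∇H², with stick walls and freeze
  outlets.
* **Statistic** — PDE = 100 × (particles deposited on the tumor surface) /
  (particles released at the trachea); a host-branch denominator variant is
  also reported.

## Worked example

```python
from mdtsim import default_config, run_case

cfg = default_config()          # 3.42 T magnet at d = 40 mm, 4 um particles
cfg.particles.n = 2000
with_magnet = run_case(cfg, seed=1)
baseline = run_case(cfg.with_overrides({"magnet.enabled": False}), seed=1)
print(f"PDE with magnet:    {with_magnet.pde:.2f}%")
print(f"PDE without magnet: {baseline.pde:.2f}%")
```

prints

```
PDE with magnet:    9.00%
PDE without magnet: 0.00%
```

i.e. with the calibrated 3.42 T bulk magnet 40 mm from the lung center
plane, roughly 9% of the released 4 µm particles deposit on the tumor cap,
versus essentially none by aerosol transport alone — the magnet turns a
negligible dose into a substantial one. (Values are Monte-Carlo estimates
with 2,000 particles; sampling error is about ±0.6 points here.)

The same pipeline is scriptable from the shell:

```bash
mdt presets list                 # calibrated magnets (2.11-10.80 T)
mdt validate-field               # Bean closed form vs Biot-Savart table
mdt simulate -c config.yaml --seed 1
mdt sweep -c config.yaml --axis d_mm --values 40,60,80,100,130 -o sweeps/
```

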