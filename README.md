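# tbfe — continuum finite-element analysis of trabecular bone strength

`tbfe` computes compressive and shear moduli of trabecular bone (Tb)
directly from calibrated CT density volumes. Instead of segmenting bone from
marrow — unreliable at clinical CT resolution, where trabeculae are thinner
than the point-spread function — it meshes *every* voxel of the volume of
interest as an 8-node hexahedral element whose nonlinear material properties
follow from the voxel's ash density:

* HU → BMD (phantom calibration line) → ρ_CHA = (ρ_BMD − 1)/(3.18 − 1)·3.18
  → ρ_ash = 0.0633 + 0.887 ρ_CHA (g/cc);
* E, S_max, S_sat as Keyak-family power laws of ρ_ash; post-yield behaviour
  by the mixed Swift–Voce law
  S(ε) = S_max + R1(1 − e^{−b(ε−ε_el)}) + R2(ε−ε_el), R1 = S_sat − S_max,
  R2 = 0, b = 10, ν = 0.3;
* displacement-controlled platen loading (bottom fixed, top driven) ramped
  in 50 sub-steps to 0.1% apparent strain, Newton–Raphson with von Mises
  radial-return plasticity;
* the Tb modulus is the slope of the linear section of mean top-surface von
  Mises stress vs applied strain, for compression and x/y shear.

Because density mass — not resolved microstructure — carries the mechanics,
these moduli reproduce well across CT scanners with different resolution.
The package includes the post-processing used to show that: Tb/marrow stress
partition (Welch t-test), normalized stress maps and loaded-bone fractions,
and two-scanner reproducibility statistics (Pearson r, ICC), plus a seeded
synthetic plate/rod phantom generator and Gaussian-PSF scanner simulator so
the entire pipeline is testable without patient data.

Audience: researchers in quantitative musculoskeletal imaging / bone
biomechanics who want a transparent, verifiable voxel-FE implementation of
segmentation-free Tb strength analysis.

## Worked example

```python
import numpy as np
from tbfe import (PhantomSpec, generate_phantom, bmd_to_ash, run_protocol,
                  partition_stats)
from tbfe.loading import element_field_to_volume
from tbfe.mesh import build_mesh

spec = PhantomSpec(grid_size=48, seed=1)        # 7.2 mm plate/rod phantom
truth, bone_mask = generate_phantom(spec)       # BMD volume + ground truth
ash = bmd_to_ash(truth)                          # full calibration chain
results = run_protocol(ash)                      # compression, x/y shear

for mode, r in results.items():
    print(f"{mode:12s} modulus = {r.modulus.modulus:7.1f} MPa "
          f"(r^2 = {r.modulus.fit_r_squared:.6f})")

mesh = build_mesh(np.ones(ash.shape, bool), ash.spacing)
vm = element_field_to_volume(mesh, results["compression"].final_state.von_mises)
p = partition_stats(vm, bone_mask)
print(f"Tb stress {p.tb_mean:.2f}±{p.tb_std:.2f} MPa vs "
      f"marrow {p.marrow_mean:.2f}±{p.marrow_std:.2f} MPa, p = {p.p_value:.2e}")
```

Output (seed 1):

```
compression  modulus =  1946.8 MPa (r^2 = 1.000000)
x_shear      modulus =  1223.5 MPa (r^2 = 1.000000)
y_shear      modulus =   288.9 MPa (r^2 = 1.000000)
Tb stress 5.63±0.40 MPa vs marrow 0.08±0.01 MPa, p = 0.00e+00
```

The compressive modulus sits in the range reported for young-adult distal
tibia (~1.6–1.7 GPa cohort means). The two shear values differ strongly from
each other because the plate phantom is anisotropic in-plane: its plates are
continuous along x and z but periodic along y, so y-shear is carried almost
entirely by the soft marrow gaps. (On real Tb networks the protocol's von
Mises-based shear construction typically *exceeds* the compressive modulus —
a pure shear stress τ contributes √3·τ to von Mises — so shear values should
only be compared within one convention.) Stress concentrates on the
trabecular network with only nominal leakage into marrow — the continuum
method's defining sanity check.

A thin CLI wraps the same calls: `tbfe run`, `tbfe phantom`, `tbfe repro`
(see `tbfe --help`).

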