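# tubeflex

Quantitative analysis of flexible helical tube assemblies — the kind of
polymer a bacteriophage tail tube protein (e.g. SPP1 gp17.1) forms: stacked
C6 rings related by a helical rise and twist, rigid enough to image at
near-atomic resolution yet flexible enough to bend. `tubeflex` bundles the
four quantitative pipelines such a study needs, each usable on its own:

1. **Relaxation dispersion** (`tubeflex.relaxation`) — estimate ¹⁵N R₁ and
   R₁ρ rates from peak-height decays, correct observed R₁ρ to on-resonance
   values in the tilted rotating frame,

   R₁ρ = (R₁ρ,obs − R₁ cos²θ) / sin²θ,  θ = tan⁻¹(ω₁/Ω),

   and fit dispersion profiles globally to a fast-exchange two-site model
   with one shared exchange rate k_ex and per-residue φ_ex = p_A p_B Δδ²
   and baseline R₁ρ,0:

   R₁ρ(ω₁) = R₁ρ,0 + φ_ex·k_ex / (ω₁² + k_ex²).

   Parameter errors come from a Monte-Carlo scheme (default 250 refits of
   perturbed data; 1000 refits for the underlying rates).

2. **Helical assembly & ambiguous restraints** (`tubeflex.assembly`) — build
   tube models from one subunit under C-symmetry plus rise/twist (defaults:
   C6, 38.46 Å, 21.89°), expand each NMR cross-peak into its 12
   symmetry-related candidate contacts over two stacked rings, combine them
   by r⁻⁶ sum averaging, check violations against a 7 Å upper bound, and
   infer β-strand registers from contact patterns.

3. **Bent-tube geometry** (`tubeflex.bent`) — rigid-arc model of a bent tube
   (bend angle = inner spacing / inner radius), harmonic restraint networks
   with straight-tube target distances, gradient relaxation under the
   network, and per-residue restraint-fulfilment scores that flag the
   stretched (hinge) regions.

4. **Density-map analytics** (`tubeflex.density`) — Gaussian-atom map
   rendering, B-factor sharpening, soft low-pass filtering, Fourier shell
   correlation between half maps, the sigmoid fit
   FSC(x) = 1/[e^((x−A)/B) + 1]^C with resolution read off at a criterion
   (0.143 for half maps), and bootstrap isosurface-variance maps that
   localise structural variability.

A seeded synthetic-data module (`tubeflex.synthetic`) generates inputs with
the statistical structure every stage assumes, so the full pipeline runs and
is tested without any experimental download.

## Worked example

Fit a shared-k_ex dispersion model to synthetic profiles generated on the
experimental spinlock grid (2–9 kHz) with k_ex = 2000 s⁻¹ and 2 % noise:

```python
from tubeflex import fit_dispersion_global, monte_carlo_errors, make_dispersion_dataset
from tubeflex.synthetic import NoiseSpec

ds = make_dispersion_dataset(2000.0,
                             phi_ex={"G43": 2.4e7, "V61": 1.1e7, "T89": 3.0e7},
                             r1rho0={"G43": 11.2, "V61": 9.4, "T89": 14.1},
                             noise=NoiseSpec(0.2, seed=7))
fit = fit_dispersion_global(ds.profiles)
fit = monte_carlo_errors(fit, ds.profiles, n_repeats=250, seed=1)
print(fit.summary())
```

```
Two-site exchange dispersion fit
========================================================
shared k_ex : 2034.47 s^-1 +/- 61.7
chi^2       : 15.0881
n residues  : 3   (MC repeats: 250)
--------------------------------------------------------
residue       phi_ex (rad^2/s^2)     R1rho_0 (1/s)
G43       2.3619e+07 +/- 6.9e+05  11.1009 +/- 0.12
V61       1.08536e+07 +/- 3.2e+05 9.16939 +/- 0.097
T89       2.94986e+07 +/- 8.7e+05  14.0094 +/- 0.13
```

The shared exchange rate is recovered within one Monte-Carlo standard
deviation of the generating 2000 s⁻¹ (a k_ex of ~2000 s⁻¹ means the two
conformers interconvert on the millisecond timescale); each residue's φ_ex
sets the depth of its dispersion decay and R₁ρ,0 its high-spinlock plateau.
`fit.plot()` draws the profiles with the fitted curves.

Geometry of the average observed curvature, from the shell:

```sh
$ tubeflex bend geometry --radius 655 --diameter 63.3 --spacing 38.5
{
  "inner_radius_A": 623.35,
  "outer_radius_A": 686.65,
  "bend_angle_deg": 3.539,
  "outer_spacing_arc_A": 42.41
}
```

A 655 Å curvature radius bends the tube by ~3.5° per ring while the inside
edge keeps its straight-tube 38.5 Å spacing — bending stretches the outside.

The full pipeline (synthetic generation → fits → assembly → bend analysis →
map analytics) runs from one seeded config and writes a hashed manifest:

```sh
tubeflex run --seed 1 --outdir runs/demo
```

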