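"""Derived biophysical constants of the reference cell file.

Builds the default parameter set (20 cells, published physiological
estimates, 0.1 nM initial load) and prints the quantities every solver is
built from.
"""

import auxinflow as ax

p = ax.default_parameters()
phys, geom = p.physiology, p.geometry

print("Geometry")
print(f"  tissue length L = {geom.L * 1e3:.4f} mm "
      f"({geom.N} cells of {geom.l * 1e6:.0f} um + "
      f"{geom.N + 1} apoplasts of {geom.lambda_ * 1e6:.1f} um)")

print("Protonation equilibria (Henderson-Hasselbalch)")
fc, fa = phys.fractions_cytoplasm, phys.fractions_apoplast
print(f"  cytoplasm (pH {phys.pH_c}): protonated fraction {fc.f_H:.4g} "
      f"-> auxin is almost entirely anionic inside cells")
print(f"  apoplast  (pH {phys.pH_a}): protonated fraction {fa.f_H:.4g} "
      f"-> a quarter of wall auxin can cross membranes passively")

print("Membrane energetics")
print(f"  phi = -F_D V / RT = {phys.phi:.4f} "
      f"(GHK rectification factor {ax.ghk_factor(phys.phi):.3f}: "
      f"the carrier strongly favours efflux)")

print("Stochastic reaction constants (per molecule, 1/s)")
k = p.rate_constants
for name, v, what in [
        ("k1=k2", k.k1, "agar block -> terminal apoplast"),
        ("k3", k.k3, "PIN efflux, cytoplasm -> downstream apoplast"),
        ("k4=k5", k.k4, "passive uptake, apoplast -> cytoplasm"),
        ("k6", k.k6, "GHK backflux (zeroed in the stochastic default)"),
        ("k7=k8", k.k7, "terminal apoplast -> agar block")]:
    print(f"  {name:6s} = {v:10.4g}   {what}")

print(f"Initial load: {p.C} molecules "
      f"(= {ax.molar_from_molecules(p.C, geom) * 1e9:.3g} nM in the source block)")
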