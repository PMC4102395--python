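"""Adiabatic reaction-coordinate scan over an analytic energy backend.

Walks the default restraint grid (1.8 Å out to 3.1 Å, back down to
0.9 Å in 0.1 Å steps) over a harmonic test surface V(r) = (r - 2.0)^2,
minimising under a stiff restraint at each target and reporting the
physical energy. The barrier is max(E) - min(E) over the profile:
transition state minus reactant complex.
"""

from p450kit.energetics import Harmonic1D, run_scan
from p450kit.qmmm import scan_restraints

legs = scan_restraints(start=1.8, lo=0.9, hi=3.1, step=0.1)
profile = run_scan(Harmonic1D(r0=2.0, a=1.0), legs)

print(f"profile points:   {len(profile.r)}")
print(f"reactant at r =   {profile.r[profile.reactant_index]:.2f} A "
      f"(E = {profile.energies[profile.reactant_index]:.4f} kcal/mol)")
print(f"highest point at  {profile.ts_coordinate:.2f} A")
print(f"barrier:          {profile.barrier:.4f} kcal/mol "
      f"(closed form V(0.9) - V(2.0) = 1.21)")
print(
    "\nThe restrained minimum sits a hair off each target because the 1000\n"
    "kcal/mol/A^2 restraint is stiff but finite; the reported energies are\n"
    "the backend's own, with the restraint term excluded."
)
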