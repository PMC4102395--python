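"""Small published input datasets bundled with the package.

These are inputs to the statistics layer (printed per-profile QM/MM
activation energies), not results computed here.
"""

# QM/MM hydrogen-abstraction barriers (kcal/mol) for oxidation at C10 of
# R-warfarin by Compound I in CYP3A4, one value per independent reaction
# profile (p1..p5), for the solubilised ("water") and membrane-bound
# ("membrane") models.
WARFARIN_H_ABSTRACTION_BARRIERS = {
    "water": (19.3, 15.9, 23.3, 20.1, 14.7),
    "membrane": (20.3, 15.0, 18.8, 14.2, 17.8),
}
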