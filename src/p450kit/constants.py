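"""Shared physical constants, naming conventions and default tables."""

# Boltzmann constant in kcal/(mol K)
KB_KCAL = 0.0019872

# IUPAC 2021 standard atomic weights, rounded to 4 significant figures.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.01,
    "N": 14.01,
    "O": 16.00,
    "P": 30.97,
    "S": 32.06,
    "Fe": 55.85,
    "Na": 22.99,
    "Cl": 35.45,
    "K": 39.10,
    "Mg": 24.31,
    "Ca": 40.08,
    "Zn": 65.38,
}

# Substrate access channels of CYP3A4 and their gating residue pairs.
# Format: name -> ((res_seq, res_name), (res_seq, res_name)).
CYP3A4_GATES = {
    "2a": ((57, "PHE"), (215, "PHE")),
    "2b": ((108, "PHE"), (220, "PHE")),
    "2c": ((108, "PHE"), (241, "PHE")),
    "2e": ((108, "PHE"), (120, "ILE")),
    "3": ((213, "PHE"), (241, "PHE")),
    "S": ((212, "ARG"), (482, "LEU")),
}

# A gate counts as open when the side-chain COM separation drops below this (Å).
GATE_OPEN_THRESHOLD = 7.0

# Residue-name conventions for solvent truncation (overridable everywhere).
WATER_RESNAMES = frozenset({"HOH", "TIP3", "SOL", "WAT"})
ION_RESNAMES = frozenset({"NA", "CL", "SOD", "CLA", "K", "POT", "MG", "CA2"})
LIPID_RESNAMES = frozenset({"POPC", "POPE"})

# Porphine core of a heme: 4 pyrrole nitrogens, 16 pyrrole carbons, 4 meso
# carbons — the 24 ring atoms kept in the QM region.
PORPHINE_RING_ATOMS = (
    "NA", "NB", "NC", "ND",
    "C1A", "C2A", "C3A", "C4A",
    "C1B", "C2B", "C3B", "C4B",
    "C1C", "C2C", "C3C", "C4C",
    "C1D", "C2D", "C3D", "C4D",
    "CHA", "CHB", "CHC", "CHD",
)

# Ring carbon -> first substituent atom for the 8 heme substituents
# (2 propionates, 2 vinyls, 4 methyls); these are the bonds severed when
# the QM region keeps the bare porphine.
HEME_SUBSTITUENT_BONDS = (
    ("C2A", "CAA"),  # propionate A
    ("C3A", "CMA"),
    ("C2B", "CMB"),
    ("C3B", "CAB"),  # vinyl B
    ("C2C", "CMC"),
    ("C3C", "CAC"),  # vinyl C
    ("C2D", "CMD"),
    ("C3D", "CAD"),  # propionate D
)

# Heme residue names and the ferryl oxygen names accepted for Compound I.
HEME_RESNAMES = frozenset({"HEM", "HEC", "HEA", "CPI"})
FERRYL_O_NAMES = ("O1", "OFE", "OXT")

# Propionate carboxylate oxygens (rings A and D) used in salt-bridge analysis.
PROPIONATE_O_NAMES = {
    "A": ("O1A", "O2A"),
    "D": ("O1D", "O2D"),
}

# Side-chain nitrogen atoms forming salt bridges / H-bonds with the
# propionates; tryptophan contributes its ring nitrogen.
SALT_BRIDGE_N_NAMES = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}

# Default salt-bridge partner residues around the CYP3A4 propionates.
CYP3A4_PROPIONATE_PARTNERS = (
    (375, "ARG"),
    (105, "ARG"),
    (130, "ARG"),
    (440, "ARG"),
    (126, "TRP"),
)
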