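"""QM/MM preparation bookkeeping on a toy Compound-I site.

Selects the QM region (iron-oxo porphine without substituents, the
proximal cysteine as SCH2, and the substrate), places hydrogen link
atoms on every severed bond, and partitions residues into mobile/fixed
by a 5 Å proximity rule.
"""

from p450kit.fixtures import make_toy_heme
from p450kit.qmmm import mobility_mask, scan_restraints, select_qm_region

site, meta = make_toy_heme(with_substrate=True)
spec = select_qm_region(site, include_substrate=True)
mask = mobility_mask(site, spec, cutoff=5.0)

print(f"toy site atoms:       {len(site)}")
print(f"QM region:            {spec.n_qm} atoms "
      f"(fixture inventory says {meta['n_qm_expected']})")
print(f"link atoms:           {len(spec.link_atoms)} "
      f"(8 ring-substituent bonds + Cys CB-CA)")
print(f"mobile atoms:         {mask.n_mobile} of {len(site)}")

up, down = scan_restraints(start=1.8, lo=0.9, hi=3.1, step=0.1)
targets = sorted({r.target for r in up} | {r.target for r in down})
print(f"scan restraints:      {len(up)} ascending + {len(down)} descending "
      f"= {len(targets)} distinct O-H targets "
      f"({targets[0]:.1f} ... {targets[-1]:.1f} A, k = 1000 kcal/mol/A^2)")
print(
    "\nEvery count is pure bookkeeping: the QM atom list, the link placements\n"
    "at 1.09 A along each severed bond, and the residue-granular mask are all\n"
    "reproducible from the structure alone."
)
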