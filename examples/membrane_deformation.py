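"""Map bilayer deformation and recover an imposed dimple.

A synthetic phosphate sheet carries a Gaussian depression of known depth
(5 Å) — the kind of local thinning a membrane shows where a protein
anchor inserts. The gridded surface in the protein-fixed frame recovers
that depth to within the binning error.
"""

import numpy as np

from p450kit.core import Selection, Trajectory
from p450kit.fixtures import make_lipid_sheet
from p450kit.membrane import deformation_surface, flat_plane_report

sheet, meta = make_lipid_sheet(
    25, 25, spacing=2.0, z0=20.0,
    deformation={"kind": "gaussian", "depth": 5.0, "sigma": 10.0},
)
p_sel = Selection(names=frozenset({"P"}))
traj = Trajectory(sheet, sheet.coords[None])
surf = deformation_surface(traj, p_sel, protein_selection=p_sel,
                           grid_spacing=2.0, split_leaflets=False)

occ = surf.occupied("upper")
zmin = float(np.nanmin(surf.mean_z["upper"][occ]))
print(f"imposed dimple depth:   {meta['deformation']['depth']:.2f} A")
print(f"recovered cell minimum: {20.0 - zmin:.2f} A below the flat level")
report = flat_plane_report(surf, "upper")
print(f"flat-plane comparison:  plane z = {report['plane_z_A']:.2f} A, "
      f"max thinning {report['max_thinning_A']:.2f} A")
print(
    "\nThe recovered minimum matches the imposed depth. The flat-plane report\n"
    "references the mean surface level instead (which the wide dimple drags\n"
    "down), the same way a planar-slab membrane model understates local\n"
    "thinning around an inserted anchor."
)
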