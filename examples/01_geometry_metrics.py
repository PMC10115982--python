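"""Geometric agreement between a candidate contour and its gold standard.

Builds a 10 mm sphere on a planning-CT-like grid, perturbs it with a known
2-voxel shift plus smooth boundary noise, and prints the metric battery.
"""

import numpy as np

from oareval import (
    PerturbationSpec,
    added_path_length,
    contour_dice,
    delta_centroid,
    delta_volume,
    generate_gs_case,
    hausdorff95,
    perturb_case,
    surface_dice,
    volumetric_dice,
    voxel_confusion,
)
from oareval.synthetic import PhantomSpec, StructurePrimitive

spec = PhantomSpec(
    spacing=(1.27, 1.27, 2.0), shape=(48, 48, 24),
    structures=(StructurePrimitive("Parotid_L", "sphere",
                                   (30.0, 30.0, 24.0), (10.0,)),),
)
case = generate_gs_case(spec, "demo")
gs = case.structset.get("Parotid_L")

arm_set, _ = perturb_case(
    case.structset,
    PerturbationSpec(translation_mm=(2.54, 0.0, 0.0), noise_amp_mm=0.8,
                     noise_corr_mm=8.0, seed=7),
    "DL",
)
cand = arm_set.get("Parotid_L")

conf = voxel_confusion(cand, gs)
print("candidate vs gold standard (2.54 mm shift + 0.8 mm boundary noise)")
print(f"  VDSC            {volumetric_dice(cand, gs):.3f}")
print(f"  SDSC(1 mm)      {surface_dice(cand, gs, 1.0):.3f}")
print(f"  SDSC(3 mm)      {surface_dice(cand, gs, 3.0):.3f}")
print(f"  HD95            {hausdorff95(cand, gs):.2f} mm")
print(f"  APL(1 mm)       {added_path_length(cand, gs, 1.0):.1f} mm")
print(f"  CDC(1 mm)       {contour_dice(cand, gs, 1.0):.3f}")
print(f"  precision       {conf.precision:.3f}")
print(f"  sensitivity     {conf.sensitivity:.3f}")
print(f"  dVolume         {delta_volume(cand, gs):+.3f} cc")
print(f"  dCentroid       {delta_centroid(cand, gs):.2f} mm")
print()
print("VDSC < 1 and a ~2.5 mm centroid shift reflect the injected"
      " translation; SDSC rises with tolerance because more of the shifted"
      " boundary falls inside the band; APL is the millimetres of gold-"
      "standard contour a clinician would still need to redraw.")
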