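"""Carry detected PF/CV points to a registered neighbouring section.

Zonated quantification of a staining of interest uses points detected in
the H&E section, moved by the dense deformation field an external WSI
registration produced.  Here a known affine field stands in for that
output.
"""

import numpy as np

import hepazone as hz

points = hz.AnnotationSet([
    hz.PointAnnotation(hz.StructureClass.CV, 120.0, 80.0),
    hz.PointAnnotation(hz.StructureClass.PF, 300.0, 240.0),
], resolution_nm_per_px=908.0)

field = hz.make_deformation_fixture(
    "affine", extent=(512, 512), grid_spacing=16,
    params={"matrix": np.array([[1.01, 0.00], [0.02, 0.99]]), "offset": (4.0, -2.0)})

moved = hz.apply_deformation(points, field)
for p, q in zip(points.points, moved.points):
    print(f"{p.cls}: ({p.x:.1f}, {p.y:.1f}) -> ({q.x:.2f}, {q.y:.2f})")
# Displacements are interpolated bilinearly from the field's grid; since the
# fixture is affine, the mapped points equal the closed-form affine image.
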