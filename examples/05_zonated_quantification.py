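"""Zonated quantification of a pericentral stain phantom.

A stain image is rendered whose optical density decreases linearly with
portality (a GS-like pericentral marker); stain deconvolution plus the
zonation maps recover a strictly decreasing 12-zone profile.
"""

import numpy as np

import hepazone as hz
import hepazone.stains as st


def unit(v):
    v = np.asarray(v, float)
    return tuple(v / np.linalg.norm(v))


layout = hz.generate_layout((1000, 1000), 300, 15, 4000, seed=2)
vectors = hz.StainVectors(unit((0.65, 0.70, 0.29)), unit((0.07, 0.99, 0.11)))
img, field = hz.render_stain_phantom(layout, lambda p: 1.0 - 0.8 * p, vectors,
                                     noise_sd=0.01, seed=3)

mask = hz.TissueMask(np.ones((1000, 1000), bool), 4000)
maps = hz.compute_zonation((1000, 1000), layout.annotation_points(), mask)
c1, _ = st.project_onto_stains(st.rgb_to_od(img), vectors)
profile = st.zonated_quantification(c1, maps)
summary = hz.zone_profile_summary(profile)

print(summary.round(3).to_string(index=False))
# Zone 1 is pericentral (p ~ 0), zone 12 periportal: the mean intensity
# falls monotonically, matching the rendered OD profile f(p) = 1 - 0.8 p.
# Intensities are uncalibrated OD-scale concentrations.
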