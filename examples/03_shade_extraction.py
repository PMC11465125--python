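"""Within-eye shade extraction for one taxon x color group.

Generates four images of a brown eye with three pigment shades
(central heterochromia: dark ring, medium body, light periphery),
then runs the full pipeline: embed, elbow-select k per image,
consensus k, re-cluster, match clusters across images by minimum SSE,
merge with pixel-count weighting, and assign dark/medium/light tiers.
"""

import numpy as np

import irisphylo as ip
from irisphylo.shades import assign_tiers, extract_group_profile, stability_curve

PLANTED = [((45, 30, 15), 0.5, "pupil ring"), ((120, 85, 50), 0.3, "body"), ((190, 150, 110), 0.2, "periphery")]

images = {
    f"img{j}": ip.gen_iris(2500, PLANTED, noise_sd=5, layout="rings", seed=j).pixels
    for j in range(4)
}

profile = extract_group_profile(images, taxon="synthetic_felid", color="brown", method="pca", seed=0)
print(f"consensus k = {profile.k} (planted: 3 shades)")
tiered = assign_tiers(profile)
print("recovered shades (planted centroids: (45,30,15), (120,85,50), (190,150,110)):")
for s in tiered.shades:
    rgb = tuple(int(round(v)) for v in s.rgb)
    print(f"  {s.tier:>6}: RGB {rgb}, {s.count} pixels, prevalence rank {s.rank}")
print(f"primary shade tier: {tiered.primary.tier!r} "
      f"(the most prevalent pigment in this eye)")

rows, converged = stability_curve(images, taxon="synthetic_felid", color="brown", seed=0)
print(f"\nstability: profile converged after {len(rows)} image prefixes -> {converged}")
print("Leveling-off of the shade RGBs with sample size indicates the images")
print("are sufficient to overcome per-image noise.")
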