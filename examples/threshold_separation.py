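"""Adaptive stain/background separation on a bimodal intensity image.

Builds an image whose pixels are drawn from a background mode at 0.2
and a staining mode at 0.8, runs the 1-D two-cluster k-means on its
intensity histogram, and prints the recovered cluster centres and the
effective threshold. No per-image manual threshold is involved.
"""
import numpy as np

import isletquant as iq

rng = np.random.default_rng(7)
values = np.concatenate([
    rng.normal(0.2, 0.05, 30_000),   # background
    rng.normal(0.8, 0.05, 10_000),   # staining
])
image = np.clip(values, 0, 1).reshape(200, 200)

stain_map = iq.separate_staining(image, histogram_bins=256)
bg, st = stain_map.cluster_centers
print(f"cluster centres:   background {bg:.3f}, staining {st:.3f}")
print(f"threshold:         {stain_map.threshold:.3f}")
print(f"stained pixels:    {stain_map.stained_mask.sum()} of {image.size} "
      f"({stain_map.stained_mask.mean():.1%}; 25% of pixels were drawn stained)")
print()
print("The threshold falls midway between the two modes, so the stained-pixel")
print("set matches the generating mixture without any hand-set cut-off.")
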