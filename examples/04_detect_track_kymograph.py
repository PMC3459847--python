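"""Puncta analytics: detection, Rayleigh-limited merging, splitting, kymograph.

Builds small labelled configurations directly, images them, and shows what
the diffraction limit does to countable puncta.
"""

import numpy as np

from omgrowth import KineticParams, OpticsConfig, detect_spots, link_tracks, render_micrograph
from omgrowth.flowfield import Patch
from omgrowth.simulator import init_state
from omgrowth.spotanalysis import kymograph_top_edge

params = KineticParams(0.004, 0.00064, 50.0)
optics = OpticsConfig()
P = 2 * np.pi * 0.5
TOP = P / 4  # arc coordinate of the cell's top edge


def band(x0, x1, label):
    v = np.array([[x0, TOP - 0.1], [x1, TOP - 0.1], [x1, TOP + 0.1], [x0, TOP + 0.1]])
    return Patch(vertices=v, label=label)


# one bright punctum ...
whole = init_state(None, params, 0)
whole.patches = [band(-0.3, 0.3, "light")]
# ... then a ~250 nm dark wedge is inserted in its middle
split = init_state(None, params, 0)
split.patches = [band(-0.3, -0.125, "light"), band(0.125, 0.3, "light"),
                 band(-0.125, 0.125, "dark")]

f0 = detect_spots(render_micrograph(whole, optics), frame=0)
f1 = detect_spots(render_micrograph(split, optics), frame=1)
print(f"before wedge: {len(f0)} punctum; after wedge: {len(f1)} puncta")

tracks = link_tracks([f0, f1], max_step_nm=300.0)
splits = [t for t in tracks if t.parent is not None]
print(f"linking annotated {len(splits)} split event (parent track "
      f"{splits[0].parent} -> child {splits[0].track_id})")

ky = kymograph_top_edge(
    [render_micrograph(whole, optics), render_micrograph(split, optics)]
)
print(f"kymograph shape (position x time): {ky.shape}; "
      f"bright columns per frame: {(ky > np.median(ky) + 20).sum(axis=0)}")
print(
    "\nA dark insertion about one PSF width wide turns one diffraction-limited\n"
    "punctum into two - the mechanism behind observed punctum splitting."
)
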