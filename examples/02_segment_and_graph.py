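"""Segment a synthetic fundus image and extract the centerline graph.

Fuses the G/R channels, segments vessels with the ridge-filter fallback,
thins the mask with Zhang-Suen, classifies endpoints/bifurcations by 3x3
neighbour counts, and measures per-point radii from the Canny edge map.
"""

import numpy as np

from fvs3d.channels import ChannelProportion, fuse_channels
from fvs3d.profiling import edges_from_mask, profile_graph
from fvs3d.segmentation import evaluate_segmentation, hysteresis_mask, \
    vesselness_segmenter
from fvs3d.skeleton import skeleton_to_graph
from fvs3d.synthetic import generate_vessel_tree, render_fundus

bundle = render_fundus(generate_vessel_tree(seed=2), seed=2)

gray = fuse_channels(bundle.image, ChannelProportion(g=1.0, r=0.0))
prob = vesselness_segmenter(gray)
mask = hysteresis_mask(prob, 0.2, 0.4)
m = evaluate_segmentation(prob, bundle.mask, threshold=0.3)
print(f"segmentation:  AUC {m.auc:.4f}  ACC {m.acc:.4f}  "
      f"SE {m.se:.3f}  SP {m.sp:.3f}")

graph = skeleton_to_graph(mask)
ends = sum(n.kind == "endpoint" for n in graph.nodes)
bifs = sum(n.kind == "bifurcation" for n in graph.nodes)
print(f"graph:         {len(graph.segments)} segments, "
      f"{ends} endpoints, {bifs} bifurcations "
      "(ground truth: 7 segments, 5 endpoints, 3 bifurcations)")

profile = profile_graph(graph, edges_from_mask(mask))
true_med = float(np.median(bundle.tree.all_radii()))
est_med = float(np.median(np.concatenate([s.radii for s in profile.segments])))
print(f"radii:         median estimate {est_med:.2f} px "
      f"vs ground truth {true_med:.2f} px")
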