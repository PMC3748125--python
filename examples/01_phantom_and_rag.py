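"""Build a synthetic phantom and inspect its region adjacency graph.

The phantom bundles a gold-standard partition, a noisy boundary-probability
cue, a region-texture cue, and a watershed oversegmentation.  The RAG has
one node per superpixel and an edge wherever two superpixels touch; every
node and edge caches cue statistics used later as merge features.
"""

import numpy as np

import aggloseg as ag

spec = ag.PhantomSpec(seed=0)
phantom = ag.make_phantom(spec)
rag = ag.build_rag(phantom.superpixels, phantom.cues)

print(f"gold segments:      {phantom.gold.max()}")
print(f"superpixels:        {len(rag)}")
print(f"rag edges:          {len(rag.edge_list())}")

u, v = rag.edge_list()[0]
stats = rag.edge_stats(u, v)
print(f"edge {(u, v)}: {rag.boundary_pixel_count(u, v)} boundary pixels, "
      f"mean boundary probability {stats.mean[0]:.3f}")
# A high mean boundary probability says the cue thinks these two
# superpixels are separated by a real membrane; agglomeration merges
# low-scoring edges first.

features = ag.pair_features(rag, u, v, ag.FeatureConfig())
print(f"merge feature vector length: {len(features)}")
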