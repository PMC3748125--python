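"""Agglomerate superpixels with the mean-boundary baseline and evaluate.

The baseline policy scores each edge by the mean boundary probability along
the shared boundary and merges edges in increasing score order up to a
threshold.  The variation of information (VI) against the gold standard
splits into a false-merge (under) and a false-split (over) term, both in
bits.
"""

import numpy as np

import aggloseg as ag
from aggloseg.agglom import cut_history

phantom = ag.make_phantom(ag.PhantomSpec(seed=0))
rag = ag.build_rag(phantom.superpixels, phantom.cues)
_, history = ag.agglomerate(rag, ag.mean_boundary_policy(), threshold=1.0)

print("threshold  segments  VI_under  VI_over  VI_total")
for t in (0.1, 0.3, 0.5, 0.7):
    seg = cut_history(history, phantom.superpixels, t)
    report = ag.vi_from_labels(seg, phantom.gold)
    print(f"{t:9.1f}  {len(np.unique(seg)):8d}  {report.under:8.3f}"
          f"  {report.over:7.3f}  {report.total:8.3f}")
# Low thresholds leave the volume oversegmented (large over term); high
# thresholds merge across weak boundary stretches (large under term).
# The best trade-off for this baseline sits well below 0.5 because the
# boundary cue fades along parts of every membrane.
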