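"""Detection metrics from per-class TP/FP/FN counts (worked example).

Counts for a whole-slide PF/CV detector evaluated against expert box
annotations (H&E test images): injecting them reproduces the familiar
precision/recall/F1 report, with the mean row averaging the unrounded class
metrics.
"""

import hepazone as hz
from hepazone.evaluation import MatchCounts

PF, CV = hz.StructureClass.PF, hz.StructureClass.CV

counts = {PF: MatchCounts(PF, 691, 196, 161),
          CV: MatchCounts(CV, 600, 139, 115)}
print(hz.metrics_table(counts).round(3).to_string(index=False))
# PF: 0.779 / 0.811 / 0.795, CV: 0.812 / 0.839 / 0.825 -> mean F1 0.810.
# Note the mean row's TP/FP/FN are arithmetic means (hence 645.5).
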