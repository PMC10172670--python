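"""Choose the number of microstate classes with GEV and the CV criterion.

Simulates data with four planted maps and scans K = 2..7: global
explained variance (GEV, higher is better) rises with K while the
cross-validation criterion (CV, lower is better) is minimized at the
true K.
"""

import numpy as np

from taskstates import select_n_maps, standard_layout_64
from taskstates.synth import make_prototype_maps, simulate_epoch

layout = standard_layout_64()
planted = make_prototype_maps(layout, k=4, seed=3)
data = np.concatenate(
    [simulate_epoch(planted, [100.0] * 4, snr=5.0, seed=i)[0].data[0]
     for i in range(3)], axis=1)

k_star, table = select_n_maps(data, k_range=(2, 7), iterations=300,
                              restarts=10, seed=0)
print(table.round(4).to_string(index=False))
print(f"CV-selected number of classes: K* = {k_star} (planted: 4)")
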