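"""Backfit a map set to an ERP and extract the four microstate parameters.

For each class: GEV (explained-variance share), mean duration (ms),
coverage (fraction of analyzed time) and occurrence (segments per
second).  Coverage always sums to 1 and occurrence x duration equals
coverage under the edge-inclusive segment convention.
"""

import numpy as np

from taskstates import backfit, compute_parameters, standard_layout_64
from taskstates.containers import ERP, time_axis
from taskstates.synth import make_prototype_maps, simulate_epoch

layout = standard_layout_64()
maps = make_prototype_maps(layout, k=6, seed=7)
epoch, truth = simulate_epoch(maps, [120, 100, 200, 80, 95, 90], snr=8.0, seed=4)

erp = ERP("demo", "negative", epoch.data[0], 500.0,
          time_axis((-200, 1000), 500.0), layout)
labels = backfit(erp, maps)
params = compute_parameters(labels, erp, maps)

print(params.to_frame().round(3).to_string(index=False))
print(f"total GEV: {params.total_gev:.3f}")
print(f"coverage sum: {params.coverage.sum():.6f}")
print("occurrence x duration == coverage:",
      np.allclose(params.occurrence * params.duration_ms / 1000.0,
                  params.coverage, atol=1e-9))
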