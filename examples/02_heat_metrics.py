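"""Chronic and acute heat metrics from daily temperature stacks.

Generates 20-year daily temperature epochs for a historical and a warmer
scenario across three climate models, computes cooling degree days, the
95th percentile of daily maxima, and hot-day frequency, and reduces the
models to their cell-wise ensemble median.
"""

import numpy as np

from elderheat import (
    SyntheticConfig,
    ensemble_median,
    generate_temperature_epoch,
    metric_surfaces,
)

config = SyntheticConfig(seed=1)

for scenario in ("historical", "ssp585"):
    per_metric = {"cdd": [], "tmax95": [], "hd": []}
    for model in range(3):
        epoch = generate_temperature_epoch(config, scenario, model_index=model)
        for name, surf in metric_surfaces(epoch).items():
            per_metric[name].append(surf)
    medians = {n: ensemble_median(s) for n, s in per_metric.items()}
    print(f"{scenario}:")
    print(f"  CDD    mean {medians['cdd'].values.mean():7.1f} degC*day/yr "
          f"(max {medians['cdd'].values.max():.1f})")
    print(f"  TMAX95 mean {medians['tmax95'].values.mean():7.2f} degC")
    print(f"  HD     mean {medians['hd'].values.mean():7.2f} days/yr "
          f"(cells with any: {np.sum(medians['hd'].values > 0)})")
# CDD accumulates daily-mean excess over 24 degC (chronic exposure);
# TMAX95 and HD describe the intensity and frequency of acute extremes
# (95th percentile of daily maxima; days at or above 37.5 degC).
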