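"""Benchmark downscaled 69+ counts against reference projections.

The generator can inject within-country heterogeneity into the elderly
growth rate — a controlled violation of the downscaling's homogeneity
assumption. Downscaled per-unit counts are then compared with the hidden
truth using absolute-percentage-error metrics.
"""

import numpy as np

from elderheat import (
    ReferenceProjection,
    SyntheticConfig,
    aggregate_to_units,
    compare,
    downscale,
    generate_population_inputs,
)

config = SyntheticConfig(seed=1)
scenario = "ssp245"

print(f"{'perturbation':>12} {'MAPE %':>8} {'pct error %':>11} "
      f"{'total error (persons)':>22}")
for level in (0.0, 0.1, 0.2, 0.4):
    inputs = generate_population_inputs(config, perturbation=level)
    projected, _, _ = downscale(
        inputs.base, inputs.total_projection[scenario],
        inputs.country_projection, scenario,
    )
    units = np.arange(projected.geometry.ncells).reshape(
        projected.geometry.shape
    )
    report = compare(
        aggregate_to_units(projected, units),
        ReferenceProjection(
            table=aggregate_to_units(inputs.truth[scenario], units),
            source="synthetic-truth", scenario=scenario,
        ),
    )
    print(f"{level:>12} {report.mape:8.3f} {report.percent_error:11.2e} "
          f"{report.total_error:22.4e}")
# MAPE grows with the injected heterogeneity while the country-total
# (percent) error stays at machine precision: the constraint always holds,
# but cell-level allocation degrades as the homogeneity assumption breaks.
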