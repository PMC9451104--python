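"""Locate a tipping point and demonstrate critical slowing near it.

Starting from the reference setting, the per-capita utility of the most
mutualistic plant type to humans is lowered until coevolution is lost.
Bisection finds the class boundary; runs near the boundary take several
times longer to settle than runs far from it.
"""

from dataclasses import replace

import hpcoevo as h

params = h.HPCParams()
axis = "utility_per_capita_type_n_plants_to_humans"

tip = h.find_tipping_point(params, axis, bracket=(0.0, 0.1))
print(f"class boundary on {axis}: {tip:.4f}")

for label, value in [
    ("far below boundary", 0.0),
    ("just below boundary", tip * 0.95),
    ("just above boundary", tip * 1.05),
    ("reference value", params.utility_per_capita_type_n_plants_to_humans),
]:
    result = h.run_summary(replace(params, **{axis: value}))
    print(f"{label:20s} ({value:.4f}): {result.end_state_class.value:20s} "
          f"t_end={result.time_end}")

# t_end grows steeply as the parameter approaches the boundary from below:
# the hallmark of a tipping point (critical slowing down).
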