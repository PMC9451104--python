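"""Run every shipped preset and compare their terminal regimes.

The four presets span the qualitative outcomes the model produces: a weakly
coupled system that stays wild, a strongly coupled one that fully
coevolves, an asymmetric one where only the human population completes the
shift, and a fully decoupled control reducing to two logistic maps.
"""

import hpcoevo as h

for preset in h.make_presets():
    result = h.run_summary(preset.params)
    marker = "ok" if result.end_state_class is preset.expected_end_state else "MISMATCH"
    print(f"{preset.name:20s} -> {result.end_state_class.value:20s} [{marker}]")
    print(f"    t_end={result.time_end:5d}  humans={result.final_state.humans:8.1f}  "
          f"plants={result.final_state.plants:8.1f}  "
          f"coevo H={result.coevolution_coefficient_humans:+.2f} "
          f"P={result.coevolution_coefficient_plants:+.2f}")

# A coevolution coefficient near +1 means the population is concentrated on
# the most mutualistic types; near -1, on the wild types. The partial preset
# ends with humans shifted (+) but plants still wild (-).
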