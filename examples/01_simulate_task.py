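"""Simulate one subject through the Go-NoGo task and inspect their learning.

Builds the default 120-trial schedule (4 conditions x 3 blocks x 10
repetitions), runs a learner with a clear Pavlovian bias through it, and
prints the per-condition accuracy plus the two descriptive bias composites.
"""

import numpy as np

from pavbias import (
    ParameterSet,
    condition_accuracy,
    descriptive_go_bias,
    descriptive_pavlovian_bias,
    generate_schedule,
    get_model,
    simulate_agent,
)

spec = get_model("RW(rew/pun)+noise+bias+pav(const)")
params = ParameterSet(spec, {"alpha": 0.25, "rho_rew": 4.0, "rho_pun": 4.0,
                             "xi": 0.1, "b": 0.4, "pi": 1.5})

rng = np.random.default_rng(0)
schedule = generate_schedule(n_blocks=3, per_cue_per_block=10, seed=rng)
session = simulate_agent(spec, params, schedule, rng)

acc = condition_accuracy(session)
print(f"simulated {session.n_trials} trials from {spec.name!r}")
for name in ("G2W", "G2AP", "NG2W", "NG2AP"):
    print(f"  accuracy {name:6s} {acc[name]:.2f}")
print(f"descriptive Pavlovian bias {descriptive_pavlovian_bias(acc):+.2f} "
      "(congruent minus incongruent accuracy; positive = reward invigorates "
      "Go)")
print(f"descriptive Go bias        {descriptive_go_bias(acc):+.2f} "
      "(Go minus NoGo accuracy)")
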