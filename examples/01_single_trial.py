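"""One trial of the two-step maze, step by step.

Builds the agent's generative model with near-veridical cues, drops the
agent at the maze entrance with the reward hidden at one of the four
final locations, and prints what it observes, believes and does at each
of the three time steps.
"""

import numpy as np

import habinf as hi

FEEDBACK_NAMES = ["cue-left", "cue-right", "reward", "punishment"]

engine = hi.Engine(hi.build_maze_model(cue_veracity=0.99))
spec = hi.volatile_spec(cue_veracity=0.99)
prior = hi.DirichletPolicyPrior.naive(7)  # no habits yet
rng = np.random.default_rng(0)

state = hi.initial_state(spec, rng)
print(f"reward hidden at final location {state.reward_location} "
      f"(context {state.context})")

record = hi.run_trial(engine, hi.expected_log_policy_prior(prior),
                      state, spec, rng)

for t, (obs, post) in enumerate(zip(record.observations, record.posteriors)):
    print(f"\ntime {t + 1}: at location {obs[0]}, sees {FEEDBACK_NAMES[obs[1]]}")
    print(f"  policy posterior: {np.array_str(post.posterior, precision=3, suppress_small=True)}")
    if t < len(record.actions):
        print(f"  action taken: {['stay', 'left', 'right'][record.actions[t][0]]}")

print(f"\nfinal location {record.final_location}; "
      f"reward obtained: {record.reward_obtained}")
print("The posterior concentrates on the policy whose action sequence "
      "explains the whole observed trajectory; that vector is the trial's "
      "habit-count increment during training.")
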