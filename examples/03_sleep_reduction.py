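"""One sleep phase in detail: Bayesian model reduction and averaging.

Takes a day on which the agent executed the first policy on all eight
trials, scores every boost-and-suppress candidate prior by its closed-form
log evidence, and shows how the evidence-weighted average forms the next
day's habit prior.
"""

import numpy as np

import habinf as hi
from habinf.bmr import sleep

prior = hi.DirichletPolicyPrior(np.array([4.0, 3.0, 1.0, 1.0, 1.0, 1.0, 1.0]))
counts = np.array([8.0, 0, 0, 0, 0, 0, 0])  # all trials ran policy 1
posterior = hi.DirichletPolicyPrior(prior.e + counts)

new_prior, audit = sleep(prior, posterior, return_audit=True)

print("candidate priors, their evidence (dF, nats) and weights:")
for i, cand in enumerate(audit):
    label = "full model " if i == 0 else f"candidate {i:2d}"
    print(f"  {label}  a'={np.array_str(cand.reduced_prior, precision=1):42s}"
          f" dF={cand.delta_F:+7.3f}  w={cand.weight:.3f}")

print(f"\nday-start prior:  {np.array_str(prior.e, precision=2)}")
print(f"day-end posterior: {np.array_str(posterior.e, precision=2)}")
print(f"post-sleep prior:  {np.array_str(new_prior.e, precision=2)}")
print("Candidates that boost the heavily-used policy carry most of the "
      "evidence, so the averaged prior strengthens it and trims the rest.")
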