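"""Profile-likelihood identifiability of the fitted parameters.

Each free parameter is scanned over a log grid while the others are
re-optimized.  A parameter is practically identifiable when the profile
rises above the optimum by the 95% chi-square threshold (3.84) on both
sides; a flat flank means the data cannot pin the parameter down.
"""

import endoctrl as ec

data = ec.default_experiment(seed=42)
result = ec.fit(data, n_starts=8, seed=0)

for name in ("k1", "a1", "alpha"):
    prof = ec.profile_likelihood(data, result.spec, result, name)
    lo, hi = prof.interval()
    print(f"{name:>6}: estimate {result.estimates[name]:10.4g}  "
          f"verdict {prof.verdict:12s}  95% range [{lo:.3g}, {hi:.3g}]")

# Expected: k1 and a1 identifiable, alpha lower-open -- shrinking alpha
# toward zero changes the day-15 fat prediction by well under the
# measurement noise, so the profile never rises on that side.
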