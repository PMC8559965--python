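"""Parameter recovery from synthetic multi-arm observations.

Generates noisy (5 % CV, lognormal) IL-6, Bcl-2 and tumor readouts for the
four treatment arms, then re-estimates the IL-6/drug coupling parameters
(lambda_2, k2, delta) by multi-start log-space least squares and reports
the relative recovery errors.
"""

from crccsim import default_parameters, fit_parameters, generate_observations
from crccsim.synthetic import recovery_report

params = default_parameters()
obs = generate_observations(params, noise_cv=0.05, n_replicates=3, seed=0)
print(f"{len(obs.data)} observations: 4 arms x 8 times x 3 observables "
      "x 3 replicates")

free = ("lambda_2", "k2", "delta")
bounds = {n: (0.25 * getattr(params, n), 4.0 * getattr(params, n))
          for n in free}
fit = fit_parameters(obs, free, bounds, n_starts=3, seed=1)
report = recovery_report(params, fit)
print(report.to_string(index=False))
print(f"loss (sum of squared log residuals): {fit.loss:.3f}")
print("\nEach free parameter dominates a distinct arm contrast: lambda_2 "
      "the\nIL-6->NF-kB gain (pinned sharply by the control arm), k2 the "
      "ATV effect\non IL-6, delta the TZB effect on Bcl-2.  k2 and delta "
      "are identified more\nweakly because the clamped doses (A=5, T=1) "
      "operate their inhibition terms\nnear saturation.")
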