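"""Global sensitivity of the model outputs to the eight uncertain
parameters.

Draws a Latin hypercube over +/-50 % ranges around the baseline, simulates
the combination arm for each sample, and prints the partial rank
correlation of each parameter with the 40-day outputs.
"""

from crccsim import default_parameters
from crccsim.sensitivity import SamplingDesign, prcc_analysis

params = default_parameters()
design = SamplingDesign.around(params, n_samples=300, seed=1)
res = prcc_analysis(design, params, eval_times=(960.0,))

df = res.to_dataframe().pivot(index="parameter", columns="output",
                              values="prcc")
print(df.round(2).to_string())
print("\nPositive coefficients mean the output rises with the parameter "
      "(rank-based,\ncontrolling for the other parameters).  IL-6 is "
      "governed by its secretion k3\nand the ATV inhibition k2; the tumor "
      "by its growth r, seeding lambda_1 and\nkill rate mu_C; BAX responds "
      "oppositely to Bcl-2 throughout.")
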