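"""Build the standardisation model that maps (k_S, delta_tau, phi) to ARI.

The ten canonical second-order model parameter combinations are
spline-interpolated to 91 grades (ARI 0.0-9.0 in 0.1 steps), each is driven
with a normalised negative pressure step, and the three model-free
parameters are measured on every response. An ordinary least-squares
regression of the generating ARI on those parameters gives the
standardisation coefficients used to score real manoeuvres.
"""

import numpy as np

from mfari import Config, fit_standardisation, generate_templates
from mfari.index import measure_template_params

templates = generate_templates()
cfg = Config()
model = fit_standardisation(templates, cfg)
X = measure_template_params(templates, cfg)

print("Standardisation regression over the 91 theoretical step responses")
print(f"  coefficients (intercept, k_S, delta_tau, phi): "
      f"({model.coef[0]:.3f}, {model.coef[1]:.3f}, {model.coef[2]:.3f}, {model.coef[3]:.3f})")
print(f"  R^2 = {model.r2:.4f}")
for name, col, unit in (("k_S", X[:, 0], ""), ("delta_tau", X[:, 1], " s"),
                        ("phi", X[:, 2], " deg")):
    print(f"  {name:10s} mean {col.mean():6.2f}{unit}  "
          f"range [{col.min():.2f}, {col.max():.2f}]{unit}")
print()
print("The regression turns the three measured descriptors of any real")
print("response into a continuous index on the familiar 0-9 ARI scale; the")
print("ranges above clamp out-of-range parameters before evaluation.")
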