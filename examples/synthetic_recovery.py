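"""Verify the analysis recovers known effects from synthetic surveys.

Generates replicate two-island surveys in which the NIS proportion truly
declines with local protection (beta_ps = -0.05 per protection level) and
rises with aquaculture (beta_aq = +0.03 per scale unit), then checks that
the regression estimates are unbiased and that 95% confidence intervals
cover the truth at their nominal rate.
"""

import numpy as np
import scipy.stats

from coastnis import SyntheticConfig, fit_mlr, generate
from coastnis.synthetic import reseeded

template = SyntheticConfig(with_abundances=False)
truth = {"status_local": template.beta_ps, "aquaculture": template.beta_aq}
n_rep = 300

est = {k: [] for k in truth}
cover = {k: 0 for k in truth}
for s in range(n_rep):
    dataset, _ = generate(reseeded(template, 1000 + s))
    m = fit_mlr(dataset, "nis_prop", ["status_local", "aquaculture", "substrate"])
    crit = scipy.stats.t.ppf(0.975, m.df2)
    for k in truth:
        est[k].append(m.coefficients[k])
        cover[k] += (
            m.coefficients[k] - crit * m.std_errors[k]
            <= truth[k]
            <= m.coefficients[k] + crit * m.std_errors[k]
        )

print(f"{n_rep} replicate surveys, 30 sites each:")
for k, beta in truth.items():
    mean = np.mean(est[k])
    print(
        f"  {k:13s} truth {beta:+.3f}  mean estimate {mean:+.4f}  "
        f"bias {100 * (mean - beta) / abs(beta):+.1f}%  "
        f"95% CI coverage {cover[k] / n_rep:.1%}"
    )
print("unbiased estimates with nominal coverage -> the linear machinery is "
      "calibrated for data of this shape")
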