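"""The clinical device-validation statistics on a synthetic error set.

BHS grading counts the fraction of absolute errors under 5/10/15 mmHg
(grade A needs 60/85/95%); the AAMI criterion requires |ME| <= 5 mmHg and
error SD < 8 mmHg; Bland-Altman reports the mean difference and the
limits of agreement (mean +/- 1.96 SD).
"""

import numpy as np

from radarbp.evaluation import (aami_check, bhs_grade, bland_altman,
                                compute_metrics, regression_stats)

rng = np.random.default_rng(0)
y_true = rng.uniform(95, 155, 400)
y_pred = y_true + rng.normal(-1.0, 4.5, 400)      # small bias, 4.5 mmHg SD

m = compute_metrics(y_true, y_pred)
print(f"ME {m.me:.2f}  MAE {m.mae:.2f}  RMSE {m.rmse:.2f}  "
      f"SD {m.sd_error:.2f} mmHg  MRE {m.mre:.2f}%  (n={m.n})")

b = bhs_grade(y_true - y_pred)
print(f"BHS cumulative <5/<10/<15 mmHg: {b.cum5:.1f}/{b.cum10:.1f}/"
      f"{b.cum15:.1f}%  -> grade {b.grade}")

a = aami_check(m.me, m.sd_error)
print(f"AAMI: ME {a.me:.2f}, SD {a.sd:.2f} -> "
      f"{'pass' if a.pass_flag else 'fail'}")

ba = bland_altman(y_true, y_pred)
print(f"Bland-Altman: mean diff {ba.mean_diff:.2f}, "
      f"LOA [{ba.loa_low:.2f}, {ba.loa_high:.2f}] mmHg")

r, r2, slope, intercept = regression_stats(y_true, y_pred)
print(f"regression: r={r:.3f}, R2={r2:.3f}, "
      f"fit y = {slope:.3f} x + {intercept:.2f}")

# An estimator with ~(-1 +/- 4.5) mmHg errors grades BHS A and passes AAMI;
# the same functions evaluate the trained pipeline's test predictions.
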