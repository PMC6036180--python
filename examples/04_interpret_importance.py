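"""Feature importance, spatial aggregation and partial dependence.

Runs the pipeline on a small cohort where age enters only through the
alpha-band oscillator amplitude, then shows that the fold-averaged
stack-weighted importance recovers the planted structure and that the top
feature's partial-dependence curves agree across folds.
"""

import logging
import warnings

from eegage.interpretation import (domain_shares, importance, pdp_all_folds,
                                   pdp_consistency)
from eegage.modeling import NCVConfig, run_ncv
from eegage.pipeline import simulate_cohort_features
from eegage.reduction import reduce_features
from eegage.simulate import SyntheticCohortSpec

warnings.filterwarnings("ignore")
logging.disable(logging.WARNING)

spec = SyntheticCohortSpec(n_subjects=50, duration=60.0, seed=5,
                           age_effects="alpha_amp")
table = simulate_cohort_features(spec).drop(columns=["sex"])
reduced, _ = reduce_features(table)
result = run_ncv(reduced, NCVConfig.fast(seed=2, k_outer=4))

imp = importance(result, reduced)
print("top 10 features by fold-averaged importance "
      "(each fold sums to 100):")
for name in imp.index[:10]:
    print(f"  {imp.loc[name, 'mean']:6.2f}  r_age={imp.loc[name, 'pearson_r_age']:+.2f}  {name}")

print("\nimportance share per domain (%):")
print(domain_shares(imp).round(1).to_string())

top = imp.index[0]
curves = pdp_all_folds(result, reduced, top)
print(f"\nPDP fold-consistency for {top}: "
      f"{pdp_consistency(curves):.3f} (mean pairwise correlation; "
      "1 = identical shapes across folds)")
print("\nWith the age signal planted only in alpha amplitude, alpha-band"
      "\nand spectral features should dominate the ranking (check the"
      "\nband/domain tokens and r_age signs above).  Note the caveat:"
      "\nwhen many surviving features are still correlated, the signal is"
      "\nspread across them, so any single feature's partial-dependence"
      "\ncurve is shallow and its fold-consistency can be poor at small n"
      "\neven while the aggregate importance ranking is stable.")
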