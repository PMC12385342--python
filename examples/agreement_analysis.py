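"""Agreement of every estimator variant against the 3-D reference.

Simulates a 67-dog mixed cohort (about one third healthy, the rest with
right-heart disease), computes indexed volumes for all eight ellipsoid
variants, and summarises agreement with the noisy 3-D reference: median
bias with its distribution-free CI, Lin's concordance correlation with its
band, and the Bland-Altman regression slope that flags proportional bias.
"""

import pandas as pd

from rvellipsoid import SyntheticConfig, compute_all_variants, generate_cohort, run_agreement

pd.set_option("display.width", 160)

cfg = SyntheticConfig(n_dogs=67, seed=1)
measurements, truth = generate_cohort(cfg)
volumes = compute_all_variants(measurements)
summary, ba_points = run_agreement(volumes)

cols = ["method", "phase", "n", "median_diff", "ccc", "band",
        "slope", "systematic_bias", "proportional_bias"]
print(summary[cols].round(4).to_string(index=False))
print("\nmedian_diff is the median of (method - reference) in mL/kg;"
      "\nccc near 1 with band 'substantial' or better means the variant tracks"
      "\nthe reference closely; proportional_bias=True means the error grows"
      "\nwith ventricular size (Bland-Altman slope CI excludes zero).")
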