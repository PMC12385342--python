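"""Demonstrate detectable proportional bias in A2C-diameter variants.

Sets the two-chamber diameter saturation exponent kappa to 0, freezing the
measured A2C diameter at its reference-volume value: enlarged ventricles
then get systematically underestimated by every variant that uses that
diameter, while RPS-diameter variants are unaffected.  The Bland-Altman
regression of differences on pairwise means picks this up as a negative
slope whose CI excludes zero.
"""

import pandas as pd

from rvellipsoid import SyntheticConfig, compute_all_variants, generate_cohort, run_agreement

pd.set_option("display.width", 160)

cfg = SyntheticConfig(n_dogs=200, seed=7, a2c_saturation_exponent=0.0)
measurements, _ = generate_cohort(cfg)
summary, _ = run_agreement(compute_all_variants(measurements))

cols = ["method", "phase", "ccc", "band", "slope", "slope_p", "proportional_bias"]
print(summary[cols].round(4).to_string(index=False))

a2c = summary[summary["method"].str.endswith("A2C")]
rps = summary[summary["method"].str.endswith("RPS")]
print(f"\nA2C-diameter variants flagged with proportional bias: "
      f"{int(a2c['proportional_bias'].sum())}/{len(a2c)}")
print(f"RPS-diameter variants flagged: {int(rps['proportional_bias'].sum())}/{len(rps)}")
print("A2C variants show strongly negative slopes (bias grows with volume)"
      "\nand drop to the 'poor' agreement band; the A4C-RPS pair keeps the"
      "\nhighest band, mirroring how a diameter that fails to track right-heart"
      "\nenlargement corrupts the ellipsoid volume estimate.")
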