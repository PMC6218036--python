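"""The agreement toolbox on its own: Meng's Z, Lin's CCC, Bland-Altman.

Simulates a criterion measurement and two competing estimators of it,
one sharper than the other, and prints the statistics a method-
comparison study would report.
"""

import numpy as np

from photobf import agreement

rng = np.random.default_rng(1)
n = 150
bf_dxa = rng.normal(32, 9, n)  # criterion %BF
bf_photo = bf_dxa + rng.normal(0, 3.0, n)  # photographic estimate
bf_nophoto = 0.8 * bf_dxa + 6 + rng.normal(0, 5.0, n)  # BMI-style baseline

z, p = agreement.meng_test(bf_dxa, bf_photo, bf_nophoto)
print(f"Meng Z = {z:.2f}, two-sided p = {p:.2g}")
print("  (tests whether the two estimators correlate *differently* with the criterion)")
print(f"Lin CCC photo    = {agreement.lin_ccc(bf_dxa, bf_photo):.3f}")
print(f"Lin CCC baseline = {agreement.lin_ccc(bf_dxa, bf_nophoto):.3f}")
print("  (1.0 would mean every point on the 45-degree line)")
ba = agreement.bland_altman(bf_dxa, bf_photo)
print(f"Bland-Altman: mean diff {ba.mean_diff:+.2f} %BF, "
      f"95% limits [{ba.loa_low:.2f}, {ba.loa_high:.2f}]")
print(f"  {100 * ba.within_limits_frac:.1f}% of paired differences fall inside the limits")
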