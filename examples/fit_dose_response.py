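"""Fit one concentration-response curve and score it.

Builds per-dose viability from a known 4PL truth (EC50 = 100 nM), refits it,
and prints the recovered parameters and the mDSS3 sensitivity score. The
score integrates excess inhibition over the tested 1-10,000 nM window, so a
curve crossing 50% viability mid-window lands mid-scale (the ceiling at the
default windows is ~88.9).
"""

from cllscreen import DEFAULT_SERIES, dss, fit_4pl, logistic4

viability = logistic4(DEFAULT_SERIES.log10_values, 100, 0, 2, 1)
print("doses (nM):     ", [f"{d:g}" for d in DEFAULT_SERIES.values_nM])
print("viability (%):  ", [f"{v:.2f}" for v in viability])

fit = fit_4pl(DEFAULT_SERIES, viability)
print(f"recovered: top={fit.top:.2f}% bottom={fit.bottom:.2f}% "
      f"EC50={10 ** fit.log_ec50:.1f} nM slope={fit.slope:.2f} "
      f"rmse={fit.rmse:.2g}")

res = dss(fit, DEFAULT_SERIES)
print(f"mDSS3 = {res.score:.2f}  (activity onset x1 = {res.x1:.2f}, "
      f"viability-10% crossing x2 = {res.x2:.2f} in log10 nM)")
print("Higher mDSS3 means higher ex vivo sensitivity to the compound.")
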