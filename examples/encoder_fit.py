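"""Fit the allometric signal-production law to a synthetic fermenter run.

The signal concentration tracks cell density as SM = a * N^b; b ~ 2 means
production is ultra-sensitive to density (per-cell share grows with N).
"""

import qscomm as q

series = q.gen_sm_series(q.SimConfig(seed=1))  # 24 points, 8 technical replicates
fit = q.fit_allometric(series)

print(f"rows below detection limit (flagged, excluded from fit): {series.below_lod.sum()}")
print(f"a = {fit.a:.2f} +- {fit.a_se:.2f} nM (a.u.)^-b   [truth 9.6]")
print(f"b = {fit.b:.3f} +- {fit.b_se:.3f}               [truth 2.09]")
print(f"=> at OD650 = 1 a.u. the signal sits near {q.sm_concentration(1.0, fit):.1f} nM;")
print("   b ~ 2: signal rises with the SQUARE of density — an ultra-sensitive encoder.")
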