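"""Quantify an unknown signal concentration from paired biosensor curves.

A calibration curve (known signal) and a sample curve (unknown spent
medium, serially diluted in signal-free medium) are both sigmoids of the
same biosensor; the unknown concentration is the horizontal offset of
their matched linear parts.  The LOD is blank mean + 3 blank SDs.
"""

import numpy as np
import pandas as pd

import qscomm as q

truth_nM = 12.0
cal_truth = q.HillParams(wmax=100.0, km=4.0, n=2.3)
rng = np.random.default_rng(1)


def measure(x_values, km, colname):
    params = q.HillParams(cal_truth.wmax, km, cal_truth.n)
    rows = [
        (x, q.hill_response(x, params) * rng.lognormal(0, 0.1) + rng.normal(0, 0.3))
        for x in x_values
        for _ in range(8)
    ]
    return pd.DataFrame(rows, columns=[colname, "response"])


cal = measure(np.append(200 / 1.5 ** np.arange(16), 0.0), cal_truth.km, "sm_nM")
sample = measure(1 / 1.5 ** np.arange(12), cal_truth.km / truth_nM, "dilution")
blanks = 10.0 + rng.normal(0, 2.0, 8)

res = q.quantify_sample(cal, sample, blanks=blanks)
print(f"undiluted sample: {res.concentration:.1f} +- {res.se:.1f} nM   [truth {truth_nM}]")
print(f"limit of detection: {res.lod:.2f} nM  (blank + 3 SD on the calibration curve)")
print(f"saturation flag: {res.saturation} (some dilutions above 80% of calibration max)")
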