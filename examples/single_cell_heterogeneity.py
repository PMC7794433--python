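"""Single-cell heterogeneity: deconvolution, hyperproducers, co-localization.

Tagged-cell fluorescence = marker + autofluorescence; the marker's
lognormal parameters are recovered by fitting the convolution with the
empirical control distribution.  Rare ~10x-bright hyperproducers are
flagged by iterative Grubbs on log-intensities, and channel coupling is
tested against a simulated independence null.
"""

import qscomm as q

pop = q.gen_cell_population(
    q.SimConfig(seed=1),
    n_cells=5000, n_control=5000,
    hyper_fraction=0.5, hyper_fold=10, channel_correlation=0.3,
)


def arr(channel, tagged):
    sub = pop[(pop.channel == channel) & (pop.tagged == tagged)]
    return sub["intensity"].to_numpy()


fit = q.deconvolve_marker(arr("yfp", True), arr("yfp", False))
print(f"YFP marker lognormal: mu_log = {fit.mu_log:.2f} [truth 5.0], "
      f"sigma_log = {fit.sigma_log:.2f} [truth 0.5], reduced chi^2 = {fit.redchi:.2f}")

report = q.detect_hyperproducers(arr("yfp", True))
print(f"hyperproducers: {report.fraction_percent:.2f}% of cells "
      f"[spiked 0.5%], ~{report.fold_brightness:.0f}x brighter than the median")


def paired(tagged):
    sub = pop[pop.tagged == tagged]
    return sub.pivot(index="cell_id", columns="channel", values="intensity")[
        ["yfp", "cfp"]
    ].to_numpy()


res = q.colocalization(
    paired(True), paired(False),
    q.LognormalParams(5.0, 0.5), q.LognormalParams(4.8, 0.5),
    n_draws=500, seed=1,
)
print(f"channel correlation: observed r = {res.r_observed:.2f}, "
      f"independence null r = {res.r_null_mean:.2f} +- {res.r_null_sd:.2f}, p = {res.p_value:.3f}")
print("   signal producers also respond more strongly (self-sensing), "
      "but the coupling is moderate.")
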