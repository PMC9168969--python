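"""Build the clinical fit, sample from it, and check which family fits.

The canonical clinical fit is a gamma distribution with mean 297 days and
SD 169 days (shape ~3.09, scale ~96.2 d). Sampling it and refitting
recovers the parameters; the Anderson-Darling bootstrap ranks gamma above
normal on gamma data.
"""

import tvdtsim as tv

fit = tv.fit_from_moments(297.0, 169.0)
print(f"clinical fit: gamma(shape={fit.shape:.4f}, scale={fit.scale:.2f} d)")

draws = tv.sample_tvdt(fit, 100_000, seed=1)
print(f"100k draws: mean {draws.mean():.1f} d, SD {draws.std(ddof=1):.1f} d "
      "(target 297 / 169)")

ranked = tv.select_family(draws[:500], n_bootstrap=200, seed=2)
for r in ranked:
    print(f"  {r.family:>6}: AD statistic {r.ad_statistic:.3f}, "
          f"bootstrap p = {r.p_value:.3f}")
print("the better-fitting family comes first")
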