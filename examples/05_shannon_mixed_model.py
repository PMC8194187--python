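"""Shannon diversity linear mixed model with marginal/conditional R2.

Models per-sample Shannon diversity on diet, sequence and their
interaction with a per-dog random intercept, then reports variance
components, Nakagawa R2, estimated marginal means per diet and
Tukey-adjusted pairwise contrasts.
"""

from crossdiet import diversity as dv
from crossdiet import mixedlm as lm
from crossdiet import simulate as sim

ds = sim.simulate_dataset(
    sim.TrialDesign(12, (0, 0)),
    sim.default_ground_truth(categories=20, phi=50.0, sigma_u=0.5,
                             depth_range=(15_000, 40_000), seed=9),
    seed=9)

rare = dv.rarefy(ds.counts, depth=12_390, seed=9)
shannon = dv.shannon(rare, base=2)

fit = lm.fit_reml(shannon, ds.metadata,
                  fixed_terms=["Diet", "Group", "Diet:Group"],
                  subject="DogID")
marginal, conditional = lm.r2_nakagawa(fit)
print(f"variance components: subject {fit.sigma2_subject:.4f}, "
      f"residual {fit.sigma2_residual:.4f}")
print(f"marginal R2 {marginal:.3f} (fixed effects alone), "
      f"conditional R2 {conditional:.3f} (fixed + dog)")

print("\nestimated marginal means by diet (95% Wald CI):")
print(lm.marginal_means(fit, "Diet").to_string(
    index=False, float_format=lambda v: f"{v:.3f}"))

print("\nTukey-adjusted pairwise diet contrasts:")
print(lm.pairwise_contrasts(fit, "Diet", adjustment="tukey")
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# A marginal R2 of ~0.3 would read as diet+sequence describing ~30% of
# the Shannon variance, the rest split between dog identity and noise.
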