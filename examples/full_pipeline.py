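"""The whole analysis end to end on a small synthetic study.

Generates ~500 community series, cleans and zero-fills them, converts air
to water temperatures, estimates species ranges from occurrence clouds,
classifies each population's temperature response, and fits the binomial
mixed models for each temperature variable x duration cell.  Artifacts are
written to ./example_run/.
"""

from fishwarm import GenerativeConfig, PipelineConfig, run_pipeline

# single-species communities and moderate noise: every population carries
# the generative signal (beta_pos = 1), so the recovered pattern is visible
# at demo scale.  With the default mixed-community, high-noise generator the
# per-population responses are mostly noise and estimates shrink toward 0.
gen = GenerativeConfig.small(
    n_series=800,
    n_sites=400,
    community_size=1,
    beta_pos=1.0,
    obs_noise_sd=0.8,
)
cfg = PipelineConfig(
    synthetic=gen,
    seed=42,
    output_dir="example_run",
    models=("position", "elevation", "trophic", "slope_sensitivity", "warming_trend"),
)
report = run_pipeline(cfg)

print("filter report:")
print(report.filter_report.to_frame().to_string(index=False))
print("\nwater warming trends (°C per decade):")
print(report.warming_trends.to_string(index=False))
print("\nposition-in-range effects (binomial GLMM, logit scale):")
print(report.position_models.to_string(index=False))
print("\ncovariate models:")
print(report.covariate_models.to_string(index=False))
print(
    "\nPositive position estimates mean populations near the poleward range"
    "\nedge are more likely to increase in abundance as water warms; here the"
    "\ngenerative log-odds slope is 1.  Estimates are attenuated most in the"
    "\nshort-duration subsets, where interannual noise misclassifies more"
    "\nresponse signs — the same pattern the duration analysis targets.  The"
    "\nelevation and trait rows are null checks: the generator encodes no"
    "\nelevation or trait effect."
)
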