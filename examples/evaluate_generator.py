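"""Score a healthy and a mode-collapsed generator with the full metric suite.

Two synthetic "generators" are simulated against the same two-mode real
feature distribution: one ideal (same mixture) and one mode-collapsed (one
of the two equal-weight modes never generated). The full protocol — FID,
KID, precision/recall, density/coverage, alpha-precision/beta-recall and
authenticity — is run on both at matched sample sizes.
"""

from synthmetrics import EvalConfig, ScenarioSpec, gen_feature_clouds, run_protocol

cfg = EvalConfig(synth_mode="matched", seed=0, kid_n_subsets=20, target_count=400)

for label, spec in [
    ("ideal generator", ScenarioSpec(n_real=400, n_synth=400, d=2, seed=0)),
    (
        "mode-collapsed generator",
        ScenarioSpec(n_real=400, n_synth=400, d=2, mode_drop=(1,), seed=0),
    ),
]:
    real, synth = gen_feature_clouds(spec)
    report = run_protocol(cfg, real, synth)
    print(f"\n{label}:")
    for metric, value in report.flat().items():
        print(f"  {metric:16s} {value:8.4f}")

# Reading the numbers: the collapsed generator keeps precision and density
# high (every sample it does produce is realistic) while recall and coverage
# drop to roughly the retained-mode mass of 0.5, alpha-precision/beta-recall
# degrade, and FID/KID rise sharply because the distributions as a whole no
# longer match. Separated fidelity/diversity metrics expose a failure that a
# single composite score would blur.
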