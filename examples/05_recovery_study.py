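"""A miniature parameter-recovery study.

Runs a scaled-down version of the recovery design (small structure, few
replications) in both scenarios — truth violating row monotonicity vs.
respecting it — and prints the bias of each estimator by the distance
between the latent and the observed level.
"""

from dataclasses import replace

from polikst import ScenarioConfig, run_recovery

base = ScenarioConfig(num_items=4, num_levels=4, structure_size=50, m=0.85,
                      n_samples=1000, n_replications=5, seed=33,
                      em_tol=1e-4, em_max_iter=300)

for scenario, monotone in ((1, False), (2, True)):
    cfg = replace(base, monotone_truth=monotone)
    report = run_recovery(cfg)
    print(f"--- scenario {scenario} "
          f"({'monotone' if monotone else 'non-monotone'} truth) ---")
    print(f"{'method':16s} {'bias |i-j|=1':>13s} {'bias |i-j|=2':>13s} "
          f"{'bias |i-j|=3':>13s} {'pi |bias|':>10s}")
    for method in ("em", "em_constrained", "md_hamming", "md_manhattan"):
        bd = report.bias_by_level_distance(method)
        pi = report.class_summary(method)["pi"]["mean_abs_bias"]
        print(f"{method:16s} {bd[1]:13.5f} {bd[2]:13.5f} {bd[3]:13.5f} "
          f"{pi:10.2e}")
# The unconstrained EM stays near zero everywhere; the constrained EM and
# the Manhattan MD over-estimate near the diagonal and under-estimate far
# from it exactly when the truth violates monotonicity (scenario 1).
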