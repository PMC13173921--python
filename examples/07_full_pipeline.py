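"""The full two-arm pipeline on a synthetic cross-platform cohort pair.

Runs preprocessing, DE, the size scan, set sampling, enrichment scoring,
balancing, forest tuning and evaluation for both the enrichment-feature
arm and the conventional expression-feature benchmark, with and without
the platform shift.
"""

from wbtdc import PipelineConfig, run_wbt_dc, simulate_cohort_pair

cfg = PipelineConfig.fast_profile(seed=3)

for label, kw in (("platform shift ON ", {}),
                  ("platform shift OFF", {"platform_shift": None})):
    tr_m, tr_p, te_m, te_p, _ = simulate_cohort_pair(seed=3, **kw)
    res = run_wbt_dc(cfg, tr_m, tr_p, te_m, te_p)
    print(f"{label}: enrichment arm AUC={res.metrics_wbtdc.roc_auc:.3f}  "
          f"conventional arm AUC={res.metrics_conventional.roc_auc:.3f}  "
          f"(set size {res.scan.chosen_size})")
# With the shift off both representations work; with it on, the raw
# expression features lose ground while the rank-based enrichment
# features barely move — the pipeline's central property.
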