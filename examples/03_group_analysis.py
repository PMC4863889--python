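"""Fit the group-by-time nested-domain model and read off contrasts.

Per-outcome effects are partially pooled toward domain-level means, which
pool toward an overarching mean; the chronic group contrast and the
time-by-group interaction are derived draw-wise (exposed minus control).
A deliberately reduced sampler budget keeps this example quick, so the
run is forced past the effective-sample-size gate that a production run
(paper_budget=True) must clear.
"""

import nestpool as npl

table, truth = npl.generate_cohort(npl.get_scenario("paper_scale", seed=7))
summary, gate = npl.run_group_analysis(
    npl.RunConfig(table=table, n_samples=8000, chains=4, n_warmup=500, seed=1, force=True)
)

print(f"summary rows: {len(summary)}  max PSRF {gate.psrf.max():.3f}  min ESS {gate.ess.min():.0f}")
rows = summary[(summary.quantity == "contrast_intercept") & (summary.level == "outcome")]
top = rows.reindex(rows["mean"].abs().sort_values(ascending=False).index).head(5)
print("\nlargest baseline contrasts (standardized; truth in brackets):")
for _, r in top.iterrows():
    print(
        f"  {r.outcome:20s} {r['mean']:+.2f} [95% HDI {r.hdi95_lo:+.2f}, {r.hdi95_hi:+.2f}]"
        f"   (true {truth.contrast_intercept[r.outcome]:+.2f})"
    )
dom = summary[(summary.quantity == "contrast_slope") & (summary.level == "domain")]
print("\ndomain-level interaction (slope) contrasts:")
for _, r in dom.iterrows():
    print(f"  {r.domain}: {r['mean']:+.3f} [95% HDI {r.hdi95_lo:+.3f}, {r.hdi95_hi:+.3f}]")
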