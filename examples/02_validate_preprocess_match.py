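"""Validate a battery table, standardize it, and pick 2:1 matched controls.

Preprocessing inverts "lower is better" columns (times, the Stroop
interference ratio), scales every outcome to mean 0 / SD 1 pooled over
groups and waves, and log10-transforms LOC duration — so fitted effects
read like partial correlation coefficients.
"""

import nestpool as npl

dmap = npl.default_domain_map()
table, _ = npl.generate_cohort(npl.CohortParams(seed=3))

report = npl.validate_battery(table, dmap)
print(f"validation: ok={report.ok}, {report.n_subjects} subjects, {report.n_rows} rows")

design, scaling = npl.orient_and_standardize(table, dmap)
print(f"design: {design.n_obs} observed cells, {design.n_outcomes} outcomes, "
      f"{design.n_domains} domains")
mean, sd, orient = scaling.outcomes["stroop_words"]
print(f"stroop_words scaling: oriented mean {mean:.1f}, sd {sd:.1f}, orientation {orient:+d} "
      "(completion time: sign-flipped so larger = better)")

# matched-control selection: exact on sex/APOE/education, nearest on age/WTAR
cases = table[table["group"] == "exposed"]
pool = table[table["group"] == "control"]
res = npl.match_controls(pool, cases, ratio=2)
print(f"\nmatching: {len(res.log)} controls selected for {cases['subject_id'].nunique()} cases")
print(res.log.head(4).to_string(index=False))
print(f"warnings: {len(res.warnings)} case(s) with fewer than 2 eligible controls")
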