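"""Group-level inference on a synthetic HC/SZ cohort.

Per-subject FA volumes carry an injected global SZ-minus-HC offset of
-0.036.  Mean FA is sampled along streamlines seeded from each midbrain
parcel and fitted with a three-way ANOVA (side x parcel x diagnosis, Type
III sums of squares); Bonferroni post-hocs compare parcels pairwise.
"""

import midparc as mp
from midparc.tracking import TrackingParams

phantom = mp.build_phantom(mp.default_phantom_spec(rng_seed=0))
cohort = mp.build_cohort(phantom, mp.CohortSpec(
    n_hc=8, n_sz=10, fa_baseline=0.47, fa_group_offset=-0.036,
    fa_noise_sd=0.05, master_seed=1))

records = []
for i, row in cohort.manifest.iterrows():
    for side in mp.SIDES:
        truth = phantom.ground_truth.territories[f"midbrain_{side}"]
        for k, lab in enumerate(mp.TERRITORY_LABELS, start=1):
            records.append(mp.sample_parcel_fa(
                truth == k, phantom.field, cohort.fa_volumes[i],
                TrackingParams(n_streamlines=2000,
                               rng_seed=1000 * i + 10 * k + (side == "R")),
                subject=row.subject, diagnosis=row.diagnosis,
                side=side, parcel=lab))

table = mp.records_to_table(records, "fa")
report = mp.run_group_analysis(table)

anova = report.anovas["fa"]
d = anova.term("diagnosis")
print(f"diagnosis effect: F({d.df_num:.0f},{d.df_den:.0f}) = {d.F:.1f}, "
      f"p = {d.p:.2g}, partial eta^2 = {d.partial_eta_sq:.3f}")
means = table.groupby("diagnosis")["value"].mean()
print(f"HC mean FA {means['HC']:.3f}, SZ mean FA {means['SZ']:.3f}, "
      f"difference {means['HC'] - means['SZ']:.3f} "
      "(the injected offset, 0.036)")
print("\nparcel post-hocs (Bonferroni):")
print(report.posthocs[("fa", "parcel")].table[
    ["level_a", "level_b", "mean_diff", "p_adj", "significant"]]
    .to_string(index=False))
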