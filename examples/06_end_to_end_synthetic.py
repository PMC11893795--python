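"""End-to-end run on a synthetic cohort with known ground truth.

Generates a 170-sample cohort (113 African, 57 European) on a toy
genome with planted pathogenic SVs and decoys, runs the full
prioritization cascade, and compares the final call set against the
planted truth.
"""

import ppsv

cohort = ppsv.generate_cohort(ppsv.SimulationConfig(seed=1))
result = ppsv.prioritize(
    cohort.sites, cohort.genes, cohort.known_table, cohort.score_panels,
    cohort.gene_sets, cohort.roles, enhancers=cohort.enhancers,
)

print("cascade funnel:")
for stage, count in result.funnel.items():
    print(f"  {stage:26s} {count:5d}")

print("\nfinal PP-SV call set:")
for sv_id, cls in sorted(result.final_pp().items()):
    call = result.calls[sv_id]
    print(f"  {sv_id:20s} {cls:11s} (rule {call.rule})")

metrics = ppsv.truth_compare(result.final_classes(), cohort.truth)["final"]
print(f"\nplanted-variant recovery: sensitivity={metrics['sensitivity']:.2f} "
      f"specificity={metrics['specificity']:.2f} "
      f"(tp={metrics['tp']}, fp={metrics['fp']})")
# Every planted pathogenic SV is recovered with its expected class and
# no decoy or background SV leaks into the final call set.
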