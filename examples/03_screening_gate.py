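"""Two-criteria screening triage on the synthetic reference cohort.

The cohort reproduces the published screening margins exactly: 921 images,
542/555 detectable per rater, 512 commonly detectable, and a 320/49/49/94
check-angle cross-tabulation.  Triage partitions every image into
appropriate / inappropriate check angle / fail detection.
"""

from collections import Counter

from grafscreen import TriageLabel, synthetic_reference_cohort, tabulate_check, tabulate_detection, triage

cohort = synthetic_reference_cohort(seed=0)
table = tabulate_detection(cohort)
pct = table.percentages()
print(f"cohort n = {table.n}")
print(f"human detectable    {table.human_detectable:4d} ({pct['human_detectable']}%)")
print(f"AI detectable       {table.ai_detectable:4d} ({pct['ai_detectable']}%)")
print(f"commonly detectable {table.commonly_detectable:4d} ({pct['commonly_detectable']}%)")
print(f"fail detection      {table.fail_detection:4d} ({pct['fail_detection']}%)")

common = [p for p in cohort if p.ai.detectable and p.human.detectable]
check = tabulate_check(common)
col = check.column_percentages()
print(f"\ncheck-angle table on the {check.n} commonly detectable images:")
print(f"  both OK {check.a}  AI-only OK {check.b}  human-only OK {check.c}  both error {check.d}")
print(f"  AI OK within human-OK column: {col['ai_ok_given_human_ok']}%")
print(f"  AI error within human-error column: {col['ai_error_given_human_error']}%")

labels = Counter(triage(p) for p in cohort)
n_app = labels[TriageLabel.APPROPRIATE]
print(f"\ntriage: appropriate {n_app} ({100 * n_app / table.n:.1f}%), "
      f"inappropriate check angle {labels[TriageLabel.INAPPROPRIATE_CHECK_ANGLE]}, "
      f"fail detection {labels[TriageLabel.FAIL_DETECTION]}")
print("Only the appropriate images enter the Graf-angle comparison.")
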