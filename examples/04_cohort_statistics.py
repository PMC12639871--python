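"""Screening-funnel arithmetic and Jeffreys-prior performance estimates.

Uses the packaged cohort count table (235,999 newborns screened) and the
confusion matrix of the 73-sample retrospective comparison.
"""

from cahlrs.stats import (CohortCounts, ConfusionCounts, cohort_metrics,
                          confusion_metrics, metrics_text)

counts = CohortCounts.packaged()
metrics = cohort_metrics(counts)
print(metrics_text(counts, metrics))

m = confusion_metrics(ConfusionCounts(tp=12, fp=0, tn=61, fn=0))
sens, spec = m["sensitivity_posterior"], m["specificity_posterior"]
print(f"sensitivity: Beta({sens.alpha}, {sens.beta}) "
      f"mean {sens.mean_percent}% "
      f"(95% CrI {sens.cri_low:.3f}-{sens.cri_high:.3f})")
print(f"specificity: Beta({spec.alpha}, {spec.beta}) "
      f"mean {spec.mean_percent}% "
      f"(95% CrI {spec.cri_low:.3f}-{spec.cri_high:.3f})")
print(f"false-positive rate: {m['fpr']}")
# With 12/12 and 61/61 correct calls the Jeffreys posterior means are
# 96.2% and 99.2%: the prior keeps the estimates off the 100% boundary,
# and the wider sensitivity interval reflects only 12 positive cases.
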