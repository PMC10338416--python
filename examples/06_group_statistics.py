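"""Factorial group comparison of per-subject median receptor levels.

Each subject contributes the median of their cPC VEGFR1 distribution; after
a skewness-gated log transform, a factorial model in sex, race and age
category (with two-way interactions) provides least-squares means, and the
post- vs premenopausal contrast is reported with its CI and Cohen's d.
"""

import numpy as np

import qflow
from qflow.stats import SampleSummary

cohort = qflow.generate_cohort(seed=6)
result = qflow.analyze_cohort(cohort)

profiles = {s.profile.subject_id: s.profile for s in cohort.subjects}
responses = np.array(
    [s.distributions[("cpc", "vegfr1")].median for s in result.subjects]
)
transform = qflow.check_and_transform(responses)
print(
    f"Shapiro-Wilk p = {transform.shapiro_p:.4f}, skewness = {transform.skewness:.2f}"
    f" -> log10 transform applied: {transform.transform_applied}"
)

summaries = []
for s, y in zip(result.subjects, transform.values):
    p = profiles[s.subject_id]
    summaries.append(
        SampleSummary(
            subject_id=s.subject_id,
            group=s.group,
            response=float(y),
            sex=p.sex,
            race=p.race,
            age_category=p.age_category,
        )
    )

model = qflow.factorial_fit(summaries)
cmp = qflow.lsmeans_contrast(model, ("female", "over50"), ("female", "under50"))
print(
    f"\npost- vs premenopausal cPC VEGFR1 (log10 scale): "
    f"estimate {cmp.estimate:.2f} [{cmp.ci_low:.2f}, {cmp.ci_high:.2f}], "
    f"p = {cmp.p_value:.4f}, Cohen's d = {cmp.cohens_d:.2f}"
)
print("A positive estimate with d >> 1.2 marks a 'very large' menopause-")
print("associated difference in membrane VEGFR1 on circulating progenitors.")
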