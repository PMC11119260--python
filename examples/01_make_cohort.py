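"""Generate a synthetic two-domain imbalanced cohort and summarise it.

Builds the default study cohort: 400 majority / 100 minority images per
domain at 32x32, with the target domain shifted by contrast 1.4 and
brightness +0.15.  Prints the per-domain class table and the fixed
template-matching separability score of each domain.
"""

import dttl
from dttl.synthetic import template_scores

cfg = dttl.SyntheticConfig(seed=0)
cohort = dttl.make_cohort(cfg)

print(dttl.cohort_summary(cohort).to_string(index=False))
# imbalance_ratio 0.25 mirrors the minority:majority ratio of real
# pneumonia screening cohorts; the target column comes from the hidden
# evaluation-only labels.

for name, images, labels in (
        ("source", cohort.source.images, cohort.source.labels),
        ("target", cohort.target_images, cohort.target_hidden_labels)):
    scores = template_scores(images, cfg)
    print(f"{name}: disc-template AUC = {dttl.auc(scores, labels):.3f}")
# Values near 1 mean a fixed matched filter separates lesion images from
# background-only images, i.e. the cohort is learnable by construction.
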