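"""Build a blinded visual Turing test and score an observer's responses.

A session mixes 50 real and 50 synthetic image references in seeded random
order; the answer key is kept separate so the observer stays blinded. The
observer's calls are scored as a confusion matrix (real = positive class)
yielding accuracy, sensitivity and specificity.
"""

import numpy as np

from synthmetrics import (
    ConfusionCounts,
    build_session,
    confusion_metrics,
    score_responses,
)

real_pool = [f"real_{i:04d}.png" for i in range(757)]
synth_pool = [f"synth_{i:05d}.png" for i in range(5000)]

session = build_session(real_pool, synth_pool, n_each=50, seed=42)
print(f"session: {len(session.items)} items, first five shown to the observer:")
for item_id, ref in session.items[:5]:
    print(f"  {item_id}: {ref}")  # note: no label visible

# simulate an observer guessing at chance
rng = np.random.default_rng(1)
responses = {
    item_id: ("real" if rng.random() < 0.5 else "synthetic")
    for item_id, _ in session.items
}
counts = score_responses(session, responses)
m = confusion_metrics(counts)
print(
    f"\nchance-level observer: TP={counts.tp} FP={counts.fp} TN={counts.tn} FN={counts.fn}"
    f"\n  accuracy={m['accuracy_2dp']} sensitivity={m['sensitivity_2dp']}"
    f" specificity={m['specificity_2dp']}"
)

# scoring a real expert reader's recorded counts (36 reals called real,
# 33 synthetics called real) gives accuracy barely above chance:
expert = confusion_metrics(ConfusionCounts(tp=36, fp=33, tn=17, fn=14))
print(
    f"\nexpert reader counts: accuracy={expert['accuracy_2dp']}"
    f" sensitivity={expert['sensitivity_2dp']} specificity={expert['specificity_2dp']}"
)
# accuracy ~0.5 means even experts cannot reliably separate real from
# synthetic images — strong perceptual fidelity of the generator
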