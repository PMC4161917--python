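"""Dual-similarity relevance feedback on a real retrieval run.

Runs the coarse-to-fine search, labels the ranked candidates against the
ground truth (standing in for a reviewer), trains the appearance-weighted
AdaBoost feedback model on the annular features, and compares the ranking
before and after feedback.
"""

import numpy as np

import hahsearch as hs
from hahsearch.features import hah_coarse
from hahsearch.feedback import FeedbackSet, rerank, train_feedback
from hahsearch.geometry import extract_patch, resize_to_query
from hahsearch.roi import RoiConfig, compute_foreground_mask, generate_candidate_windows
from hahsearch.search import coarse_cascade, fine_rank

R = 3
img, truth = hs.make_smear_fixture(hs.FixtureConfig(seed=0))
query = hs.query_from_truth(img, truth, "neutrophil")

mask = compute_foreground_mask(img)
cands = generate_candidate_windows(mask, query, RoiConfig())
fine = fine_rank(query, coarse_cascade(query, cands, img, R), img, R)
top = fine.entries[:100]
print(f"{len(cands)} candidate windows -> {len(fine)} cascade survivors; "
      f"feedback on the top {len(top)}")

# reviewer stand-in: a retrieved window is "relevant" if it lands on a
# planted object of the query's class
relevant_windows = [o.window for o in truth.of_class("neutrophil")]
labels = np.array([
    any(w.iou(t) >= 0.25 for t in relevant_windows) for w, _ in top
])
feats = np.array([
    hah_coarse(resize_to_query(extract_patch(img, w), query.w, query.h), R)
    for w, _ in top
])
items = FeedbackSet([w for w, _ in top], feats,
                    np.array([d for _, d in top]), labels)

model = train_feedback(items)
ranked = rerank(model, items)
by_id = {id(w): l for w, l in zip(items.windows, items.labels)}
p10_before = labels[:10].mean()
p10_after = np.mean([by_id[id(w)] for w, _ in ranked.entries[:10]])
print(f"PCA kept {model.pca.k} components "
      f"({model.pca.explained_variance_ratio.sum():.1%} of variance), "
      f"{len(model.stumps)} boosting rounds")
print(f"precision@10 before feedback: {p10_before:.2f}")
print(f"precision@10 after feedback:  {p10_after:.2f}")
# feedback should keep or sharpen the head of the ranking: visually
# similar relevant items get both label and appearance weight
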