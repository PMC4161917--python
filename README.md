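# hahsearch

Content-based retrieval of similar patches in histopathology images.

Pathologists reviewing digitized specimens routinely need every region that
looks like a given example — every neutrophil in a blood smear, every
necrotic glomerulus in a renal section. `hahsearch` takes a query patch and
finds visually similar patches across one or many microscopy images, using
a color feature that is sensitive to *where* colors sit inside a patch, a
cascade search that discards most candidates cheaply, and an optional
relevance-feedback stage that folds reviewer labels back into the ranking.

## Method

**Feature.** A patch is divided into `r` consecutive concentric rectangular
rings (ring 1 innermost). The coarse descriptor concatenates the per-ring
normalized RGB histograms,

    H_c = (h_1, ..., h_r),        dim(H_c) = 256 x 3 x r,

and the fine descriptor further splits each ring into 8 angular octants,

    H_f = (h_{1,1}, ..., h_{r,8}),   dim(H_f) = 256 x 3 x r x 8.

Two patches with identical global color content but different spatial
layout (say, dark center vs dark border) are identical to a plain color
histogram but far apart under `H_c`. Similarity is Euclidean distance
`D_i = ||H(q) - H(v_i)||`.

**Search.** Stained foreground is masked by optical-density color
deconvolution + Otsu thresholding + morphology; candidate windows slide
over it with overlap ratio in [0.5, 0.9] (optionally at scales
½, 1, 2, 3, 4 times the query, resampled to query geometry). The coarse
cascade then scores ring 1 only and keeps the top `ceil(n/2)`, appends ring
2 and halves again, and so on to ring `r` — so half of all candidates are
dismissed after a single ring histogram. Survivors are re-ranked by `H_f`,
and the best-ranked 10% are fused by flat-kernel mean-shift on window
centers with bandwidth `b = sqrt(w^2 + h^2)/2`, yielding one detection mode
per retrieved site. Gabor filter-bank and gray-level co-occurrence features
are included as classical texture baselines for comparison.

**Relevance feedback.** The top-`K` retrievals (default 100) are labeled
relevant / non-relevant. Their coarse features are PCA-reduced to the
smallest basis holding ≥ 90% of the variance, and a discrete AdaBoost
ensemble of decision stumps is trained with the *initial sample
distribution* set by appearance: `W_i ∝ (1 - D̃_i) + 1/K`, where `D̃_i` is
the min-max-normalized distance to the query — labels and visual
similarity enter the classifier together. Items are re-ranked by ensemble
margin.

Per-image searches are independent, so multi-image queries run as a bag of
tasks consumed by pull-model workers whose merged output is identical to a
serial run.

No clinical images ship with the package: a seeded fixture module
generates blood-smear-like and renal-tissue-like fields with exact ground
truth, which all tests and evaluations run against.

## Worked example

```python
import hahsearch as hs
from hahsearch.search import SearchConfig, run_search

img, truth = hs.make_smear_fixture(hs.FixtureConfig(seed=0))
query = hs.query_from_truth(img, truth, "neutrophil")
result = run_search([img], query, SearchConfig())[0]
same = truth.of_class("neutrophil")
hits = sum(1 for o in same
           if any(rep.iou(o.window) >= 0.25 for rep in result.representatives))
print(f"{len(result.modes)} modes, recovered {hits}/{len(same)}")
```

Running `python examples/03_hierarchical_search.py` (this pipeline with
per-mode detail) prints:

```
query: 38x38 px window at (412.5, 298.5)
mean-shift bandwidth: 26.9 px
27 retrieval modes:
  mode at (  18.5,  949.5)  1 fused windows, best window at (0, 931)
  ...
recovered 4/5 planted neutrophil-like cells (recall 80%)
```

Each mode is one fused detection site; a planted cell counts as recovered
when a mode's best-ranked window overlaps its true location. The other
examples demonstrate the annular feature's spatial discrimination
(`02`), feedback re-ranking — precision@10 rising from 0.40 to 0.90 on a
labeled run (`04`), evaluation curves (`05`) and parallel execution (`06`).

A thin CLI mirrors the library: `hahsearch fixtures make`, `search run`,
`feedback rerank`, `eval pr|roc|recall`.

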