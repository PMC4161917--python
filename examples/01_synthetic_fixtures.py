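"""Generate the two synthetic fixture types and inspect their ground truth.

Builds a blood-smear-like field (five leukocyte-like classes among dense
erythrocyte-like distractors) and a renal-tissue-like field (intact vs
degraded ring structures at several scales), both fully determined by a
seed, and prints what was planted where.
"""

import collections

import hahsearch as hs
from hahsearch.fixtures import renal_config

smear_img, smear_truth = hs.make_smear_fixture(hs.FixtureConfig(seed=0))
print(f"smear field: {smear_img.shape[1]}x{smear_img.shape[0]} px, "
      f"{len(smear_truth.objects)} planted cells")
counts = collections.Counter(o.label for o in smear_truth.objects)
for label, n in counts.most_common():
    print(f"  {label:12s} {n}")
# the class mix follows the adult differential: neutrophils dominate

renal_img, renal_truth = hs.make_renal_fixture(renal_config(seed=0))
print(f"\nrenal field: {renal_img.shape[1]}x{renal_img.shape[0]} px, "
      f"{len(renal_truth.objects)} glomerulus-like objects")
for o in renal_truth.objects:
    r, c = o.window.center
    print(f"  {o.label:9s} scale {o.scale:<4} at ({r:.0f}, {c:.0f})")
# every object's window, class and scale is recorded, so retrieval
# precision and recall can be scored exactly against this truth
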