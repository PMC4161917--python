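"""Pull-model execution of a multi-image query.

Searches ten fixture fields for one query with a shared task queue, first
serially and then with four workers, and verifies the merged results are
identical — the contract that makes worker count a pure throughput knob.
"""

import json
import time

import hahsearch as hs
from hahsearch.parallel import execute_pull, merged_records, plan_tasks
from hahsearch.search import SearchConfig

images, query = [], None
for seed in range(10):
    cfg = hs.FixtureConfig(height=220, width=220, n_objects=2,
                           class_mix={"neutrophil": 1.0},
                           distractor_count=110, seed=seed)
    img, truth = hs.make_smear_fixture(cfg)
    images.append(img)
    if query is None:
        query = hs.query_from_truth(img, truth, "neutrophil")

tasks = plan_tasks(images, query, SearchConfig())
print(f"{len(tasks)} independent tasks, ids {tasks[0].task_id}..{tasks[-1].task_id}")

t0 = time.perf_counter()
serial = merged_records(execute_pull(tasks, images, query, workers=1))
t1 = time.perf_counter()
parallel = merged_records(execute_pull(tasks, images, query, workers=4))
t2 = time.perf_counter()

n_modes = sum(len(r["modes"]) for r in serial)
print(f"serial:   {t1 - t0:.2f}s, {n_modes} retrieval modes across all images")
print(f"4 workers: {t2 - t1:.2f}s")
print(f"merged results identical: {json.dumps(serial) == json.dumps(parallel)}")
# idle workers pull the next task from the queue, so heterogeneous task
# durations balance themselves; the merge is ordered by task id and does
# not depend on which worker ran what
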