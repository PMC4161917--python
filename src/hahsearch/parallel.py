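"""Local master/worker task execution with a pull model.

Per-image searches are independent, so a whole-dataset query is a bag of
tasks.  Idle workers pull the next task from a shared queue — heterogeneous
task durations balance themselves — and the master merges per-image results
in task order, so the merged output is identical to a serial run regardless
of worker count.  A failed task is re-queued once, then reported failed.
"""

from __future__ import annotations

import logging
import queue
import threading
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import QueryPatch
from .search import ClusterResult, SearchConfig, run_search

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchTask:
    """One unit of work: search a single image for the query."""

    task_id: str
    image_index: int
    config: SearchConfig


@dataclass
class TaskOutcome:
    task_id: str
    result: ClusterResult | None
    error: str | None = None
    duration_s: float = 0.0


def plan_tasks(
    images: Sequence[np.ndarray],
    query: QueryPatch,
    config: SearchConfig | None = None,
) -> list[SearchTask]:
    """One task per image with deterministic, stable ids."""
    if not len(images):
        raise ValueError("plan_tasks needs at least one image")
    config = config or SearchConfig()
    return [
        SearchTask(task_id=f"task-{i:05d}", image_index=i, config=config)
        for i in range(len(images))
    ]


def _run_one(
    task: SearchTask, images: Sequence[np.ndarray], query: QueryPatch
) -> ClusterResult:
    return run_search(
        [images[task.image_index]], query, task.config,
        image_ids=[str(task.image_index)],
    )[0]


def execute_pull(
    tasks: Sequence[SearchTask],
    images: Sequence[np.ndarray],
    query: QueryPatch,
    workers: int = 1,
    task_fn: Callable[[SearchTask, Sequence[np.ndarray], QueryPatch], ClusterResult] | None = None,
) -> dict[str, TaskOutcome]:
    """Execute ``tasks`` with ``workers`` pull-model workers.

    Returns ``{task_id: TaskOutcome}``.  ``workers=1`` runs serially in the
    calling thread (the reference execution); more workers share a queue,
    each pulling the next task when idle.  A task that raises is re-queued
    once; a second failure is recorded in the outcome.  ``task_fn`` is
    injectable for testing (defaults to the per-image search).
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    fn = task_fn or _run_one
    outcomes: dict[str, TaskOutcome] = {}
    lock = threading.Lock()

    def attempt(task: SearchTask, retried: bool) -> bool:
        """Run one task; record the outcome; return True to re-queue."""
        t0 = time.perf_counter()
        try:
            result = fn(task, images, query)
        except Exception as exc:
            if not retried:
                logger.warning("task %s failed (%s); re-queuing once", task.task_id, exc)
                return True
            with lock:
                outcomes[task.task_id] = TaskOutcome(
                    task.task_id, None, error=str(exc),
                    duration_s=time.perf_counter() - t0,
                )
            logger.error("task %s failed twice: %s", task.task_id, exc)
            return False
        with lock:
            outcomes[task.task_id] = TaskOutcome(
                task.task_id, result, duration_s=time.perf_counter() - t0
            )
        return False

    if workers == 1:
        for task in tasks:
            if attempt(task, retried=False):
                attempt(task, retried=True)
        return outcomes

    q: queue.Queue = queue.Queue()
    for task in tasks:
        q.put((task, False))

    def worker() -> None:
        while True:
            try:
                task, retried = q.get_nowait()
            except queue.Empty:
                return
            if attempt(task, retried):
                q.put((task, True))
            q.task_done()

    threads = [threading.Thread(target=worker, daemon=True) for _ in range(workers)]
    for t in threads:
        t.start()
    q.join()
    for t in threads:
        t.join(timeout=5)
    return outcomes


def merged_records(outcomes: dict[str, TaskOutcome]) -> list[dict]:
    """Merge outcomes into one JSON-ready list, ordered by task id so the
    result is independent of execution order."""
    records = []
    for task_id in sorted(outcomes):
        out = outcomes[task_id]
        records.append(
            {
                "task_id": task_id,
                "error": out.error,
                "modes": out.result.to_records() if out.result is not None else None,
            }
        )
    return records
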