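"""Block-design task schedules.

The experiment is a four-condition block design: Rest (contrast), MV (move
hand + vibrotactile stimulation), MO (move hand + observe video), and MOV
(all three combined). Tasks last 10 s, separated by rests drawn uniformly
from 25-30 s, organised in sessions of equal length. Condition counts are
balanced globally: a pool with ``total/4`` blocks per condition is shuffled
with the seed and chunked into sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CONDITIONS", "TaskBlock", "TaskSchedule", "generate_schedule"]

CONDITIONS = ("Rest", "MV", "MO", "MOV")


@dataclass(frozen=True)
class TaskBlock:
    session: int
    condition: str
    onset: float  # s, on the continuous recording time axis
    duration: float  # s


@dataclass(frozen=True)
class TaskSchedule:
    """Ordered task blocks over one continuous multi-session recording."""

    blocks: tuple[TaskBlock, ...]
    inter_task_rest: tuple[float, float] = (25.0, 30.0)

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(b.condition for b in self.blocks)

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.blocks:
            counts[b.condition] = counts.get(b.condition, 0) + 1
        return counts

    @property
    def end_time(self) -> float:
        last = self.blocks[-1]
        return last.onset + last.duration


def generate_schedule(
    n_sessions: int,
    tasks_per_session: int,
    rng_seed: int,
    *,
    conditions: tuple[str, ...] = CONDITIONS,
    task_duration: float = 10.0,
    rest_range: tuple[float, float] = (25.0, 30.0),
    initial_rest: float = 30.0,
    session_gap: float = 180.0,
) -> TaskSchedule:
    """Generate a balanced, randomized block schedule.

    Parameters
    ----------
    n_sessions, tasks_per_session
        Session structure; the total must be divisible by the number of
        conditions so that every condition occurs equally often.
    rng_seed
        Seed for the shuffle and the rest-interval draws; identical seeds
        give identical schedules.
    initial_rest
        Quiet interval before the first onset of each session, s.
    session_gap
        Break between sessions appended to the time axis, s.

    Returns
    -------
    TaskSchedule
        Blocks with strictly increasing onsets; consecutive onsets within a
        session are separated by ``task_duration`` plus a rest drawn
        uniformly from ``rest_range``.
    """
    total = n_sessions * tasks_per_session
    k = len(conditions)
    if total % k != 0:
        raise ValueError(
            f"{n_sessions} x {tasks_per_session} tasks cannot be balanced "
            f"over {k} conditions"
        )
    rng = np.random.default_rng(rng_seed)
    pool = [c for c in conditions for _ in range(total // k)]
    order = rng.permutation(total)
    shuffled = [pool[i] for i in order]

    blocks: list[TaskBlock] = []
    t = 0.0
    for s in range(n_sessions):
        t += initial_rest
        for j in range(tasks_per_session):
            cond = shuffled[s * tasks_per_session + j]
            blocks.append(TaskBlock(session=s, condition=cond, onset=t, duration=task_duration))
            rest = float(rng.uniform(*rest_range))
            t += task_duration + rest
        t += session_gap
    return TaskSchedule(blocks=tuple(blocks), inter_task_rest=rest_range)
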