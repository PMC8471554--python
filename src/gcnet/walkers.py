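"""Monte Carlo random-walk sampling of GC maps.

A walk starts at a uniform-random node (counted as its first visitation) and
repeatedly jumps to a successor drawn with probability proportional to the
current node's outgoing GC weights, until ``max_steps`` visitations have been
recorded or the walk lands on a dangling node (no surviving outgoing edges),
which terminates the chain early. The whole process restarts ``restarts``
times and visitations accumulate across restarts.

Variants:

* ``direction="reverse"`` transposes the map first, so tokens travel "uphill"
  toward generators of activity.
* ``metric="interval"`` tracks, per node, the gaps between consecutive
  visitations within one restart (a visit followed by three other nodes and
  then a revisit records an interval of 4); gaps never carry across restarts,
  and nodes revisited in no restart have an undefined mean interval and rank
  last.
* ``tokens=k`` walks k tokens synchronously from independent uniform starts
  and records a visitation at a node only when all k tokens coincide there
  (including at the start positions); a restart ends as soon as any token
  occupies a dangling node.

Implementation note — RNG contract: one ``numpy`` generator seeded from
``cfg.seed`` drives the run. All restarts advance in lockstep (the chains are
independent, so they can be vectorised across restarts); draws are consumed
in a fixed documented order — first the start nodes for every restart/token,
then one batch of uniforms per step covering every restart and token, drawn
even for already-terminated chains so the stream layout never depends on the
graph. Same seed + same config => bit-identical outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gcmap import GCMap, reverse, to_transition
from .ranking import NodeRanking, make_ranking

__all__ = [
    "WalkConfig",
    "WalkOutcome",
    "sample",
    "interval_metric",
    "multi_token_sample",
    "outcome_to_metric",
]


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of one sampling run.

    ``max_steps`` bounds the number of visitations per restart (the start
    node counts as the first); for multi-token walks it bounds the number of
    synchronous coincidence checks per restart, which reduces to the same
    rule at ``tokens=1``.
    """

    restarts: int = 1000
    max_steps: int = 1000
    direction: str = "forward"
    metric: str = "count"
    tokens: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1 or self.max_steps < 1 or self.tokens < 1:
            raise ValueError("restarts, max_steps and tokens must all be >= 1")
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")
        if self.metric not in ("count", "interval"):
            raise ValueError("metric must be 'count' or 'interval'")
        if self.metric == "interval" and self.tokens != 1:
            raise ValueError("the interval metric is defined for a single token")


@dataclass
class WalkOutcome:
    """Accumulated visitation statistics of one sampling run."""

    labels: list[str]
    visit_counts: np.ndarray
    mean_intervals: np.ndarray  # NaN where undefined (node never revisited)
    completed_restarts: int
    truncated_restarts: int
    config: WalkConfig


def _draw_next(cum: np.ndarray, rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    # inverse-CDF draw per chain; cum rows of dangling nodes are never used
    idx = (cum[rows] <= u[..., None]).sum(axis=-1)
    return np.minimum(idx, cum.shape[0] - 1)


def sample(g: GCMap, cfg: WalkConfig) -> WalkOutcome:
    """Run the Monte Carlo sampling walk described in the module docstring."""
    if g.n == 0:
        raise ValueError("cannot sample an empty graph")
    if cfg.direction == "reverse":
        g = reverse(g)
    tm = to_transition(g)
    n = g.n
    cum = np.cumsum(tm.probs, axis=1)
    is_dangling = np.zeros(n, dtype=bool)
    if tm.dangling:
        is_dangling[list(tm.dangling)] = True

    rng = np.random.default_rng(cfg.seed)
    R, S, k = cfg.restarts, cfg.max_steps, cfg.tokens
    track_intervals = cfg.metric == "interval"

    pos = rng.integers(0, n, size=(R, k))
    active = np.ones(R, dtype=bool)
    counts = np.zeros(n, dtype=np.int64)
    if track_intervals:
        last_visit = np.full((R, n), -1, dtype=np.int64)
        gap_sum = np.zeros(n, dtype=np.float64)
        gap_cnt = np.zeros(n, dtype=np.int64)

    for t in range(S):
        act = np.flatnonzero(active)
        if act.size:
            if k == 1:
                v = pos[act, 0]
                np.add.at(counts, v, 1)
                if track_intervals:
                    prev = last_visit[act, v]
                    seen = prev >= 0
                    np.add.at(gap_sum, v[seen], (t - prev[seen]).astype(float))
                    np.add.at(gap_cnt, v[seen], 1)
                    last_visit[act, v] = t
            else:
                together = (pos[act] == pos[act, :1]).all(axis=1)
                np.add.at(counts, pos[act[together], 0], 1)
        if t == S - 1:
            break
        # chains with any token on a dangling node stop here (the landing
        # visitation above was still recorded)
        stopping = active & is_dangling[pos].any(axis=1)
        active &= ~stopping
        u = rng.random((R, k))  # drawn for every chain to fix the stream layout
        act = np.flatnonzero(active)
        if act.size:
            pos[act] = _draw_next(cum, pos[act], u[act])
        elif not active.any() and t < S - 2:
            # all chains dead: consume the remaining per-step draws in one go
            rng.random((S - 2 - t, R, k))
            break

    truncated = int((~active).sum())
    mean_intervals = np.full(n, np.nan)
    if track_intervals:
        has = gap_cnt > 0
        mean_intervals[has] = gap_sum[has] / gap_cnt[has]
    return WalkOutcome(list(g.labels), counts, mean_intervals, R - truncated, truncated, cfg)


def interval_metric(g: GCMap, cfg: WalkConfig) -> WalkOutcome:
    """Sampling run tracking mean revisit intervals (metric="interval")."""
    if cfg.metric != "interval":
        cfg = replace(cfg, metric="interval")
    return sample(g, cfg)


def multi_token_sample(g: GCMap, cfg: WalkConfig) -> WalkOutcome:
    """Sampling run with k >= 2 synchronous tokens recording coincidences."""
    if cfg.tokens < 2:
        raise ValueError("multi_token_sample needs tokens >= 2")
    return sample(g, cfg)


def outcome_to_metric(o: WalkOutcome, metric: str | None = None) -> NodeRanking:
    """Turn a WalkOutcome into a NodeRanking.

    ``count``: visitation counts, most-visited node ranks 1. ``interval``:
    mean revisit intervals, shortest interval ranks 1, undefined (NaN)
    intervals rank after every defined one.
    """
    metric = metric or o.config.metric
    if metric == "count":
        values = o.visit_counts.astype(float)
        higher_is_better = True
    elif metric == "interval":
        values = o.mean_intervals
        higher_is_better = False
    else:
        raise ValueError("metric must be 'count' or 'interval'")
    name = "walk-" + metric + ("" if o.config.tokens == 1 else f"-{o.config.tokens}tok")
    return make_ranking(
        o.labels,
        values,
        name,
        direction=o.config.direction,
        higher_is_better=higher_is_better,
    )
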