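"""Stimulus sets and counterbalanced trial sequences for the four experiments.

The bisection experiments use seven tone durations log-spaced from 1 to 4 s,
presented in a first-order counterbalanced sequence: every ordered pair of
consecutive durations (including repeats) occurs equally often.  Such a
sequence is exactly an Eulerian circuit on the complete directed graph with
self-loops over the duration set (n^2 = 49 transitions per block), which is
how ``counterbalanced_sequence`` constructs it.  The reproduction experiment
uses seven linearly spaced durations (1000..4000 ms, 500-ms steps) in eight
42-trial blocks alternating free-movement and hold encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 3 x 3 grid of candidate start locations for the reproduction experiment,
#: spanning a 10-cm square centred on the origin.
GRID_3X3 = [(x, y) for y in (-5.0, 0.0, 5.0) for x in (-5.0, 0.0, 5.0)]


@dataclass
class DesignSpec:
    """A fully expanded experimental design.

    ``trials`` is one row per trial with columns at least
    (block, trial, duration_ms, condition, start_x, start_y).
    """

    durations_ms: list[float]
    reps_per_duration: int
    n_blocks: int
    experiment: str
    seed: int
    trials: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = np.asarray(self.durations_ms, float)
        if not np.all(np.diff(d) > 0):
            raise ValueError("durations must be strictly increasing")


def log_spaced_durations(t_min_ms: float, t_max_ms: float, n: int) -> np.ndarray:
    """Geometric progression of ``n`` durations from t_min to t_max inclusive."""
    if n < 2:
        raise ValueError("need at least 2 durations")
    if not (0 < t_min_ms < t_max_ms):
        raise ValueError("need 0 < t_min < t_max")
    return np.geomspace(t_min_ms, t_max_ms, n)


def linear_durations_reproduction() -> np.ndarray:
    """The reproduction experiment's seven durations: 1000..4000 ms in 500-ms steps."""
    return np.arange(1000.0, 4001.0, 500.0)


def _random_eulerian_circuit(n_items: int, start: int, rng: np.random.Generator) -> list[int]:
    """Node sequence (length n_items**2) of a random Eulerian circuit on the
    complete digraph with self-loops; consecutive pairs, read cyclically,
    cover every ordered pair exactly once.

    Hierholzer's algorithm with randomized edge order.  The graph has
    in-degree = out-degree = n_items at every node, so a circuit exists.
    """
    # remaining out-neighbours per node, shuffled
    out = {u: list(rng.permutation(n_items)) for u in range(n_items)}
    stack = [start]
    circuit: list[int] = []
    while stack:
        u = stack[-1]
        if out[u]:
            stack.append(out[u].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()  # closed walk: circuit[0] == circuit[-1] == start
    assert circuit[0] == circuit[-1] == start
    return circuit[:-1]


def counterbalanced_sequence(n_items: int, n_blocks: int, seed: int) -> np.ndarray:
    """First-order counterbalanced item sequence of length n_blocks * n_items**2.

    Each block is an independently randomized Eulerian circuit starting at a
    common (seed-chosen) node, so each block is cyclically first-order
    balanced and the concatenation, read cyclically, contains every ordered
    pair (i, j) exactly ``n_blocks`` times.
    """
    if n_items < 1 or n_blocks < 1:
        raise ValueError("n_items and n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    if n_items == 1:
        return np.zeros(n_blocks, dtype=np.int64)
    start = int(rng.integers(n_items))
    seq: list[int] = []
    for _ in range(n_blocks):
        seq.extend(_random_eulerian_circuit(n_items, start, rng))
    return np.asarray(seq, dtype=np.int64)


def bisection_design(durations_ms=None, n_blocks: int = 8, seed: int = 0,
                     experiment: str = "bisection_free",
                     condition: str | None = None,
                     start_xy: tuple[float, float] = (0.0, 0.0)) -> DesignSpec:
    """Expanded trial list for a bisection experiment (default: 8 blocks x 49)."""
    if durations_ms is None:
        durations_ms = log_spaced_durations(1000, 4000, 7)
    durations_ms = np.asarray(durations_ms, float)
    n = len(durations_ms)
    if condition is None:
        condition = "free" if experiment == "bisection_free" else "hold"
    idx = counterbalanced_sequence(n, n_blocks, seed)
    per_block = n * n
    trials = pd.DataFrame({
        "block": np.repeat(np.arange(n_blocks), per_block),
        "trial": np.tile(np.arange(per_block), n_blocks),
        "duration_ms": durations_ms[idx],
        "condition": condition,
        "start_x": start_xy[0],
        "start_y": start_xy[1],
    })
    return DesignSpec(list(durations_ms), reps_per_duration=n_blocks * n,
                      n_blocks=n_blocks, experiment=experiment, seed=seed, trials=trials)


def twostart_design(close_cm: float = 7.8, far_cm: float = 10.0,
                    n_blocks_per_distance: int = 8, seed: int = 0) -> DesignSpec:
    """Two-start-distance bisection design: 392 trials at each start distance.

    The start location is shifted along the 90-deg axis so that the start is
    ``close_cm`` (resp. ``far_cm``) from both targets; blocks alternate
    distance.  Positions are expressed in the far-start frame (targets at
    10 cm from the far start).
    """
    base = log_spaced_durations(1000, 4000, 7)
    rng = np.random.default_rng(seed)
    order = ["close", "far"] if rng.integers(2) else ["far", "close"]
    frames = []
    for b in range(2 * n_blocks_per_distance):
        dist_label = order[b % 2]
        d_cm = close_cm if dist_label == "close" else far_cm
        # chord half-angle: targets at 105/75 on the 10-cm circle around far start
        half = 10.0 * np.sin(np.radians(15.0))
        y_off = 10.0 * np.cos(np.radians(15.0)) - np.sqrt(d_cm**2 - half**2)
        sub = bisection_design(base, n_blocks=1, seed=int(rng.integers(2**31)),
                               experiment="bisection_hold_twostart", condition="hold",
                               start_xy=(0.0, y_off)).trials
        sub["block"] = b
        sub["start_distance"] = dist_label
        frames.append(sub)
    trials = pd.concat(frames, ignore_index=True)
    return DesignSpec(list(base), reps_per_duration=2 * n_blocks_per_distance * 7,
                      n_blocks=2 * n_blocks_per_distance,
                      experiment="bisection_hold_twostart", seed=seed, trials=trials)


def reproduction_block_design(n_testing_blocks: int = 8, reps_per_block: int = 6,
                              seed: int = 0) -> DesignSpec:
    """Reproduction design: 8 testing blocks of 42 trials (7 durations x 6 reps),
    alternating free-movement and hold encoding (counterbalanced starting
    condition), start locations drawn from the 3 x 3 grid with the
    reproduction-phase start never repeating the encoding start.
    """
    durations = linear_durations_reproduction()
    n_dur = len(durations)
    block_len = reps_per_block * n_dur
    if block_len != 42 and n_dur == 7 and reps_per_block * 7 != block_len:
        raise ValueError("reps_per_block x 7 must equal the block length")
    rng = np.random.default_rng(seed)
    first = "free" if rng.integers(2) else "hold"
    rows = []
    grid = np.asarray(GRID_3X3)
    for b in range(n_testing_blocks):
        cond = first if b % 2 == 0 else ("hold" if first == "free" else "free")
        durs = rng.permutation(np.repeat(durations, reps_per_block))
        for t, d in enumerate(durs):
            enc = int(rng.integers(len(grid)))
            rep = int(rng.integers(len(grid) - 1))
            if rep >= enc:
                rep += 1  # reproduction start drawn from the remaining 8 locations
            rows.append({
                "block": b, "trial": t, "duration_ms": d, "condition": cond,
                "start_x": grid[enc, 0], "start_y": grid[enc, 1],
                "repro_start_x": grid[rep, 0], "repro_start_y": grid[rep, 1],
            })
    trials = pd.DataFrame(rows)
    return DesignSpec(list(durations), reps_per_duration=n_testing_blocks * reps_per_block,
                      n_blocks=n_testing_blocks, experiment="reproduction",
                      seed=seed, trials=trials)
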