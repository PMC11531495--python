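"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here (BFS flood fill, brute-force prominence
calculator, per-frame O(n^2) neighbor scan, brute-force distance transform)
deliberately share no code with the package so they can serve as independent
references.
"""

from collections import deque

import numpy as np
import pandas as pd
import pytest

from condensig.synthetic_data import (
    KtrSimConfig,
    PunctaSceneConfig,
    simulate_ktr_dataset,
    simulate_puncta_scene,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def bfs_flood_fill(above: np.ndarray, seed: tuple[int, int], connectivity: int = 8):
    """Breadth-first flood fill over a boolean grid from a seed pixel."""
    if not above[seed]:
        return set()
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    h, w = above.shape
    seen = {seed}
    queue = deque([seed])
    while queue:
        r, c = queue.popleft()
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and above[rr, cc] and (rr, cc) not in seen:
                seen.add((rr, cc))
                queue.append((rr, cc))
    return seen


def brute_force_peaks(y: np.ndarray, min_prominence: float, min_distance: int):
    """Direct local-maximum scan with textbook topographic prominence.

    Returns sorted (index, prominence) pairs after the same highest-priority
    minimum-distance filtering used by standard peak finders.
    """
    n = len(y)
    candidates = []
    for i in range(1, n - 1):
        if not (y[i] > y[i - 1] and y[i] > y[i + 1]):
            continue
        j, lmin = i - 1, y[i]
        while j >= 0 and y[j] <= y[i]:
            lmin = min(lmin, y[j])
            j -= 1
        k, rmin = i + 1, y[i]
        while k < n and y[k] <= y[i]:
            rmin = min(rmin, y[k])
            k += 1
        prom = y[i] - max(lmin, rmin)
        candidates.append((i, prom))
    # distance filtering runs over all local maxima (highest first), before
    # the prominence threshold is applied
    kept: list[tuple[int, float]] = []
    for i, prom in sorted(candidates, key=lambda t: -y[t[0]]):
        if all(abs(i - j) >= min_distance for j, _ in kept):
            kept.append((i, prom))
    return sorted((i, p) for i, p in kept if p >= min_prominence)


def brute_force_edge(mask: np.ndarray, ring_width: float) -> np.ndarray:
    """Edge ring by exhaustive per-pixel Euclidean distance to the complement."""
    h, w = mask.shape
    comp = np.argwhere(~mask)
    edge = np.zeros_like(mask)
    for r, c in np.argwhere(mask):
        d = np.sqrt(((comp - [r, c]) ** 2).sum(axis=1)).min()
        edge[r, c] = d <= ring_width
    return edge


def brute_force_neighbors(
    trace_df: pd.DataFrame,
    dying_cell: int,
    death_frame: int,
    radius: float,
    window: int = 10,
) -> set[int]:
    """Per-frame O(n^2) neighbor scan straight off the tidy trace table.

    Re-derives own-segment spans and death frames from the raw table,
    independent of the package's trace objects.
    """
    last_frame = trace_df.groupby("cell_id")["frame"].max()
    death = {
        int(c): int(g.loc[g["died_this_frame"] == 1, "frame"].iloc[0])
        for c, g in trace_df.groupby("cell_id")
        if (g["died_this_frame"] == 1).any()
    }
    own_start = {}
    for cell, grp in trace_df.groupby("cell_id"):
        parent = grp["parent_id"].iloc[0]
        own_start[int(cell)] = (
            int(last_frame[int(parent)]) + 1 if not pd.isna(parent) else int(grp["frame"].min())
        )
    pos = {
        (int(r.cell_id), int(r.frame)): (r.x_px, r.y_px)
        for r in trace_df.itertuples()
    }

    def alive(cell, frame):
        if frame < own_start[cell] or frame > last_frame[cell]:
            return False
        return cell not in death or frame <= death[cell]

    neighbors = set()
    for f in range(death_frame - window, death_frame):
        if not alive(dying_cell, f) or (dying_cell, f) not in pos:
            continue
        x0, y0 = pos[(dying_cell, f)]
        for cell in last_frame.index:
            cell = int(cell)
            if cell == dying_cell or not alive(cell, f) or (cell, f) not in pos:
                continue
            x1, y1 = pos[(cell, f)]
            if np.hypot(x0 - x1, y0 - y1) <= radius:
                neighbors.add(cell)
    return neighbors


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def puncta_scene():
    """Default two-channel condensate scene (9 cells, 5 puncta/cell, 5x gain)."""
    cfg = PunctaSceneConfig(seed=3)
    img_a, img_b, truth = simulate_puncta_scene(cfg)
    return cfg, img_a, img_b, truth


@pytest.fixture(scope="session")
def ktr_dataset():
    """Default 22-h KTR dataset (150 starting cells, 264 frames)."""
    cfg = KtrSimConfig(seed=5)
    trace_df, truth = simulate_ktr_dataset(cfg)
    return cfg, trace_df, truth
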