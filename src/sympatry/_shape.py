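"""Shape primitives shared by the dive planter and the dive detector.

Depth is metres, positive down.  The bottom phase of a dive is the interval
from the first to the last sample at or below ``frac`` (default 80%) of the
maximum depth; wiggles are complete vertical oscillations inside that phase;
plateaus are slow-vertical-speed shelves outside it.
"""
from __future__ import annotations

import numpy as np

from .exceptions import DegenerateDiveError

BOTTOM_FRAC = 0.8
WIGGLE_EXCURSION = 2.0       # m
PLATEAU_MIN_DURATION = 5.0   # s
PLATEAU_MAX_SPEED = 0.25     # m/s
PLATEAU_MIN_DEPTH = 3.0      # m
_EPS = 1e-9


def bottom_phase(depths: np.ndarray, dt: float, frac: float = BOTTOM_FRAC
                 ) -> tuple[int, int, float]:
    """Indices of the first/last sample within the bottom band and the
    elapsed bottom time (s)."""
    if depths.size < 3:
        raise DegenerateDiveError("dive segment shorter than 3 samples")
    band = frac * depths.max()
    idx = np.nonzero(depths >= band - _EPS)[0]
    i0, i1 = int(idx[0]), int(idx[-1])
    return i0, i1, (i1 - i0) * dt


def count_wiggles(depths: np.ndarray, i0: int, i1: int,
                  excursion: float = WIGGLE_EXCURSION) -> int:
    """Complete oscillations (ascent >= excursion followed by descent >=
    excursion, or the inverse) within the bottom phase.  Each full
    up-and-down excursion counts once."""
    seg = depths[i0:i1 + 1]
    if seg.size < 3:
        return 0
    wiggles = 0
    pending = False
    cur_max = seg[0]
    cur_min = np.inf
    for v in seg[1:]:
        if not pending:
            cur_max = max(cur_max, v)
            if cur_max - v >= excursion - _EPS:   # rose away from the bottom
                pending = True
                cur_min = v
        else:
            cur_min = min(cur_min, v)
            if v - cur_min >= excursion - _EPS:   # returned back down
                wiggles += 1
                pending = False
                cur_max = v
    return wiggles


def smooth3(depths: np.ndarray) -> np.ndarray:
    """3-point moving average with reflected edges (length preserved)."""
    padded = np.pad(depths, 1, mode="edge")
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def vertical_speed(depths: np.ndarray, dt: float, half_window: int = 3
                   ) -> np.ndarray:
    """Centred vertical-speed estimate (m/s) over +-half_window samples of
    the 3-point-smoothed trace; edges are marked infinitely fast so they can
    never qualify as plateaus."""
    s = smooth3(depths)
    v = np.full(depths.shape, np.inf)
    h = half_window
    if depths.size > 2 * h:
        v[h:-h] = (s[2 * h:] - s[:-2 * h]) / (2 * h * dt)
    return v


def find_plateaus(depths: np.ndarray, dt: float, i0: int, i1: int,
                  min_duration: float = PLATEAU_MIN_DURATION,
                  max_speed: float = PLATEAU_MAX_SPEED,
                  min_depth: float = PLATEAU_MIN_DEPTH
                  ) -> list[tuple[int, int]]:
    """Maximal runs outside the bottom phase that are deeper than
    ``min_depth``, slower than ``max_speed`` and at least ``min_duration``
    long.  Returns (start, stop) index pairs (stop exclusive)."""
    if depths.size < 3:
        raise DegenerateDiveError("dive segment shorter than 3 samples")
    v = vertical_speed(depths, dt)
    ok = (np.abs(v) <= max_speed + _EPS) & (depths > min_depth)
    ok[i0:i1 + 1] = False
    min_samples = int(np.ceil(min_duration / dt))
    runs = []
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_samples:
                runs.append((start, i))
            start = None
    return runs
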