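"""Two-round stage-drift correction on spot coordinates.

The instrument revisits each FOV at every imaging event; mechanical stage
error translates the whole event by an integer number of pixels.  Correction
works on detected spot *coordinates*, not on images: every molecule is
visible in the initial-position (fill-and-lock) image, so those positions
serve as anchors, and the per-event translation is the one that maximises
the number of spots landing within one pixel (Chebyshev, i.e. a 3×3
neighbourhood) of an anchor.

Round 1 estimates offsets against all anchors.  Anchors that match spots in
the largest number of round-1-corrected incorporation events — the top 10 %
by default — become *position markers*, and round 2 re-estimates every
offset against the markers only.  Using only frequently-incorporating
molecules as markers suppresses the influence of non-specific spots and
stalled molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnchorSet",
    "anchors_from_spots",
    "estimate_offset",
    "select_markers",
    "correct_run",
]

DRIFT_COLUMNS = [
    "fov_id",
    "quad",
    "flow",
    "phase",
    "dx_px",
    "dy_px",
    "match_count",
    "round",
    "low_confidence",
]


@dataclass
class AnchorSet:
    """Anchors (initial molecule positions) with optional marker designation.

    ``anchors`` has columns (anchor_id, fov_id, x_px, y_px); ``marker_ids``
    is the subset used as position markers in round 2.
    """

    anchors: pd.DataFrame
    marker_ids: set[int] = field(default_factory=set)

    def for_fov(self, fov_id: int, markers_only: bool = False) -> pd.DataFrame:
        sel = self.anchors[self.anchors.fov_id == fov_id]
        if markers_only:
            sel = sel[sel.anchor_id.isin(self.marker_ids)]
        return sel

    def __len__(self) -> int:
        return len(self.anchors)


def anchors_from_spots(spots: pd.DataFrame) -> AnchorSet:
    """Build the anchor set from the initial-position image (event quad 0).

    Every spot in the fill-and-lock image defines one anchor — including any
    non-specific spot, exactly as on the instrument, where the anchor set
    cannot be distinguished from noise at this stage.
    """
    init = spots[(spots.quad == 0) & (spots.phase == "incorporation")]
    anchors = (
        init[["fov_id", "x_px", "y_px"]]
        .drop_duplicates()
        .sort_values(["fov_id", "x_px", "y_px"])
        .reset_index(drop=True)
    )
    anchors.insert(0, "anchor_id", np.arange(len(anchors)))
    return AnchorSet(anchors=anchors)


def _coords(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table[["x_px", "y_px"]].to_numpy(dtype=int)
    return np.asarray(table, dtype=int).reshape(-1, 2)


def _dilated_grid(targets: np.ndarray, pad: int) -> tuple[np.ndarray, int, int]:
    """Boolean grid marking the 3×3 neighbourhood of each target.

    Returns (grid, x0, y0) with grid[y - y0, x - x0] True iff (x, y) lies
    within Chebyshev distance 1 of a target.
    """
    x0 = int(targets[:, 0].min()) - pad - 1
    y0 = int(targets[:, 1].min()) - pad - 1
    w = int(targets[:, 0].max()) - x0 + pad + 2
    h = int(targets[:, 1].max()) - y0 + pad + 2
    grid = np.zeros((h, w), dtype=bool)
    for ddx in (-1, 0, 1):
        for ddy in (-1, 0, 1):
            grid[targets[:, 1] - y0 + ddy, targets[:, 0] - x0 + ddx] = True
    return grid, x0, y0


def _shift_order(window_px: int) -> np.ndarray:
    """All integer shifts in the window, sorted by (|dx|+|dy|, dx, dy)."""
    r = np.arange(-window_px, window_px + 1)
    dx, dy = np.meshgrid(r, r, indexing="ij")
    shifts = np.column_stack([dx.ravel(), dy.ravel()])
    order = np.lexsort((shifts[:, 1], shifts[:, 0], np.abs(shifts).sum(axis=1)))
    return shifts[order]


def estimate_offset(
    event_spots, targets, window_px: int = 8
) -> tuple[int, int, int]:
    """Estimate the drift of one imaging event against target positions.

    Exhaustively scores every integer translation (dx, dy) in
    ``[-window_px, window_px]²``.  Stage drift is an integer translation and
    spot coordinates are integers, so translations are ranked primarily by
    the number of *exact* coordinate matches to a target, then by the number
    of spots within Chebyshev distance 1 of a target (the one-pixel-tolerance
    score, which alone is ±1-ambiguous: all nine translations around the true
    drift tie on it), then by smallest |dx|+|dy|, then lexicographically on
    (dx, dy).  Returns ``(dx, dy, match_count)`` with ``match_count`` the
    one-pixel-tolerance score of the chosen translation.  An empty spot
    table (or empty target set) yields (0, 0, 0).
    """
    if window_px < 0:
        raise ValueError("window_px must be >= 0")
    spots = _coords(event_spots)
    targ = _coords(targets)
    if len(spots) == 0 or len(targ) == 0:
        return (0, 0, 0)
    grid, x0, y0 = _dilated_grid(targ, window_px)
    exact = np.zeros_like(grid)
    exact[targ[:, 1] - y0, targ[:, 0] - x0] = True
    shifts = _shift_order(window_px)
    sx = spots[:, 0][None, :] - shifts[:, 0][:, None] - x0
    sy = spots[:, 1][None, :] - shifts[:, 1][:, None] - y0
    inside = (sx >= 0) & (sx < grid.shape[1]) & (sy >= 0) & (sy < grid.shape[0])
    hit = np.zeros_like(inside)
    hit[inside] = grid[sy[inside], sx[inside]]
    counts = hit.sum(axis=1)
    hit_exact = np.zeros_like(inside)
    hit_exact[inside] = exact[sy[inside], sx[inside]]
    exact_counts = hit_exact.sum(axis=1)
    # shifts are pre-sorted by (|dx|+|dy|, dx, dy); lexsort is stable, so the
    # first element of the best (exact_count, count) class wins the tie-break
    order = np.lexsort((-counts, -exact_counts))
    best = int(order[0])
    dx, dy = (int(v) for v in shifts[best])
    return (dx, dy, int(counts[best]))


def select_markers(anchor_match_counts: dict[int, int], fraction: float = 0.10) -> list[int]:
    """Select the top ``fraction`` of anchors by match count as markers.

    Takes the top ``ceil(fraction * n)`` anchors; ties at the boundary are
    broken by ascending anchor_id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not anchor_match_counts:
        return []
    k = int(np.ceil(fraction * len(anchor_match_counts)))
    ranked = sorted(anchor_match_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [aid for aid, _ in ranked[:k]]


def _match_flags(corrected: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Per-anchor flag: does any corrected spot fall within Chebyshev <= 1."""
    if len(corrected) == 0:
        return np.zeros(len(anchors), dtype=bool)
    grid, x0, y0 = _dilated_grid(corrected, 0)
    ax = anchors[:, 0] - x0
    ay = anchors[:, 1] - y0
    ok = (ax >= 0) & (ax < grid.shape[1]) & (ay >= 0) & (ay < grid.shape[0])
    out = np.zeros(len(anchors), dtype=bool)
    out[ok] = grid[ay[ok], ax[ok]]
    return out


def correct_run(
    spots: pd.DataFrame,
    anchors: AnchorSet,
    window_px: int = 8,
    marker_fraction: float = 0.10,
    min_marker_matches: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-round drift correction of a whole run's spot tables.

    Round 1 estimates each imaging event's offset against all anchors of its
    FOV; per-anchor match counts over the round-1-corrected incorporation
    events then select the markers; round 2 re-estimates every offset against
    markers only and the round-2 offsets are applied to all spots (including
    post-cleave images, each corrected with its own event's estimate).

    A round-2 estimate supported by fewer than ``min_marker_matches`` marker
    matches (an event that happens to contain few marker molecules) falls
    back to the event's round-1 offset; estimates whose final support is
    still below ``min_marker_matches`` are flagged ``low_confidence`` but
    applied anyway — sparse events never fail.

    Returns ``(corrected_spots, drift_estimates)``.
    """
    if len(anchors) == 0:
        raise ValueError("anchor set must be non-empty")
    drift_rows: list[tuple] = []
    corrected = spots.copy()
    events = (
        spots[["fov_id", "quad", "flow", "phase"]]
        .drop_duplicates()
        .sort_values(["fov_id", "quad", "flow", "phase"])
        .itertuples(index=False)
    )
    events = [tuple(e) for e in events]
    by_event = {k: g for k, g in spots.groupby(["fov_id", "quad", "flow", "phase"])}

    # round 1: against all anchors; accumulate per-anchor match counts over
    # corrected incorporation events
    round1: dict[tuple, tuple[int, int, int]] = {}
    match_counts: dict[int, int] = {
        int(a): 0 for a in anchors.anchors.anchor_id
    }
    fov_anchor_cache: dict[int, pd.DataFrame] = {}
    for ev in events:
        fov = ev[0]
        fa = fov_anchor_cache.setdefault(fov, anchors.for_fov(fov))
        ev_spots = by_event[ev]
        if ev[1] == 0 and ev[3] == "incorporation":
            est = (0, 0, len(ev_spots))  # initial image defines the origin
        else:
            est = estimate_offset(ev_spots, fa, window_px)
        round1[ev] = est
        if ev[3] == "incorporation" and ev[1] > 0:
            corr = _coords(ev_spots) - np.array(est[:2])
            flags = _match_flags(corr, _coords(fa))
            for aid, flag in zip(fa.anchor_id.to_numpy(), flags):
                if flag:
                    match_counts[int(aid)] += 1

    # markers are selected per FOV so every FOV keeps its own top fraction
    marker_ids: set[int] = set()
    for fov, fa in fov_anchor_cache.items():
        counts = {int(a): match_counts[int(a)] for a in fa.anchor_id}
        marker_ids.update(select_markers(counts, marker_fraction))
    anchors.marker_ids = marker_ids

    # round 2: against markers only; final correction
    for ev in events:
        fov = ev[0]
        fm = anchors.for_fov(fov, markers_only=True)
        ev_spots = by_event[ev]
        if ev[1] == 0 and ev[3] == "incorporation":
            dx, dy, mc = 0, 0, len(ev_spots)
        else:
            dx, dy, mc = estimate_offset(ev_spots, fm, window_px)
            if mc < min_marker_matches:  # too few markers seen: keep round 1
                dx, dy, mc = round1[ev]
        low = mc < min_marker_matches
        idx = ev_spots.index
        corrected.loc[idx, "x_px"] = spots.loc[idx, "x_px"] - dx
        corrected.loc[idx, "y_px"] = spots.loc[idx, "y_px"] - dy
        r1 = round1[ev]
        drift_rows.append((*ev, r1[0], r1[1], r1[2], 1, False))
        drift_rows.append((*ev, dx, dy, mc, 2, bool(low)))

    drift = pd.DataFrame(drift_rows, columns=DRIFT_COLUMNS)
    return corrected, drift
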