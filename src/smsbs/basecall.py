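"""Assemble per-molecule reads from drift-corrected spot tables.

After drift correction every incorporation-phase spot is matched to the
anchor (initial molecule position) it lies within one pixel of; the sequence
of flow bases of a given anchor's spots, in flow order, is its read.  Reads
whose anchor shows a persisting dye in post-cleave images are excluded
(cleave failure), and short or byproduct reads are filtered before
identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import FlowSchedule
from .register import AnchorSet

__all__ = [
    "CalledRead",
    "assign_spots",
    "call_reads",
    "filter_reads",
]

ASSIGNMENT_COLUMNS = [
    "fov_id",
    "quad",
    "flow",
    "phase",
    "x_px",
    "y_px",
    "anchor_id",
    "molecule_id",
]


@dataclass
class CalledRead:
    """A single-molecule read with per-base flow provenance."""

    anchor_id: int
    fov_id: int
    x_px: int
    y_px: int
    seq: str
    base_provenance: list[tuple[int, int]]  # (quad, flow) per base
    stopped_at_quad: int
    excluded_reason: str = "none"  # none | cleave_failure
    byproduct: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def read_id(self) -> str:
        """Spatially traceable identifier: FOV, anchor and pixel position."""
        return f"fov{self.fov_id}_a{self.anchor_id}_x{self.x_px}_y{self.y_px}"

    @staticmethod
    def parse_read_id(read_id: str) -> tuple[int, int, int, int]:
        """Inverse of :attr:`read_id` → (fov_id, anchor_id, x_px, y_px)."""
        import re

        m = re.fullmatch(r"fov(\d+)_a(\d+)_x(-?\d+)_y(-?\d+)", read_id)
        if not m:
            raise ValueError(f"unparseable read id {read_id!r}")
        return tuple(int(g) for g in m.groups())  # type: ignore[return-value]


def assign_spots(
    corrected_spots: pd.DataFrame, anchors: AnchorSet, tolerance_px: int = 1
) -> pd.DataFrame:
    """Assign drift-corrected spots to anchors within a pixel tolerance.

    A spot is assignable to anchors within Chebyshev distance
    ``tolerance_px`` and is assigned to the nearest candidate by Euclidean
    distance; an exact distance tie leaves the spot unassigned.  Each anchor
    accepts at most one spot per imaging event — the nearest wins and losers
    stay unassigned.  Unassigned spots are recorded with ``anchor_id = -1``
    (non-specific).
    """
    if tolerance_px < 0:
        raise ValueError("tolerance_px must be >= 0")
    out_rows: list[tuple] = []
    has_mol = "molecule_id" in corrected_spots.columns
    for fov, fov_spots in corrected_spots.groupby("fov_id"):
        fa = anchors.for_fov(fov)
        pos_to_anchor = {
            (int(x), int(y)): int(a)
            for a, x, y in zip(fa.anchor_id, fa.x_px, fa.y_px)
        }
        for (quad, flow, phase), ev in fov_spots.groupby(["quad", "flow", "phase"]):
            # spot -> (anchor, squared distance); None = unassigned
            cand: list[tuple[int, int, int, int, int | None, int]] = []
            for idx, s in enumerate(ev.itertuples(index=False)):
                x, y = int(s.x_px), int(s.y_px)
                best_a, best_d, tie = None, None, False
                for ddx in range(-tolerance_px, tolerance_px + 1):
                    for ddy in range(-tolerance_px, tolerance_px + 1):
                        a = pos_to_anchor.get((x + ddx, y + ddy))
                        if a is None:
                            continue
                        d = ddx * ddx + ddy * ddy
                        if best_d is None or d < best_d:
                            best_a, best_d, tie = a, d, False
                        elif d == best_d and a != best_a:
                            tie = True
                mol = int(getattr(s, "molecule_id", -1)) if has_mol else -1
                a = -1 if (best_a is None or tie) else best_a
                cand.append((x, y, mol, a, best_d if a != -1 else None))
            # anchor contention: nearest spot wins, distance ties unassign all
            by_anchor: dict[int, list[int]] = {}
            for i, (_, _, _, a, _) in enumerate(cand):
                if a != -1:
                    by_anchor.setdefault(a, []).append(i)
            final = [a for (_, _, _, a, _) in cand]
            for a, idxs in by_anchor.items():
                if len(idxs) > 1:
                    dists = [cand[i][4] for i in idxs]
                    dmin = min(dists)
                    winners = [i for i, d in zip(idxs, dists) if d == dmin]
                    for i in idxs:
                        final[i] = -1
                    if len(winners) == 1:
                        final[winners[0]] = a
            for (x, y, mol, _, _), a in zip(cand, final):
                out_rows.append((fov, quad, flow, phase, x, y, a, mol))
    return pd.DataFrame(out_rows, columns=ASSIGNMENT_COLUMNS)


def call_reads(
    assignments: pd.DataFrame,
    schedule: FlowSchedule,
    anchors: AnchorSet,
    cleave_fail_quads: int = 1,
) -> list[CalledRead]:
    """Transform per-anchor spot assignments into called reads.

    ``assignments`` holds both incorporation- and post-cleave-phase rows (as
    produced by :func:`assign_spots` on the full corrected table).  A read's
    sequence is the flow bases of its anchor's incorporation spots in flow
    order; anchors with assigned post-cleave spots in at least
    ``cleave_fail_quads`` distinct quads are excluded as cleave failures.
    Anchors with no incorporation spot yield retained length-0 reads.
    """
    base_of = {(fl.quad, fl.flow): fl.base for fl in schedule}
    inc = assignments[
        (assignments.phase == "incorporation")
        & (assignments.quad >= 1)
        & (assignments.anchor_id >= 0)
    ]
    pc = assignments[
        (assignments.phase == "post_cleave") & (assignments.anchor_id >= 0)
    ]
    inc_by_anchor = {a: g for a, g in inc.groupby("anchor_id")}
    pc_quads = pc.groupby("anchor_id")["quad"].nunique().to_dict()

    reads: list[CalledRead] = []
    for a in anchors.anchors.itertuples(index=False):
        aid = int(a.anchor_id)
        g = inc_by_anchor.get(aid)
        if g is None:
            prov: list[tuple[int, int]] = []
        else:
            g = g.sort_values(["quad", "flow"])
            prov = [(int(q), int(f)) for q, f in zip(g.quad, g.flow)]
        seq = "".join(base_of[qf] for qf in prov)
        excluded = (
            "cleave_failure"
            if pc_quads.get(aid, 0) >= cleave_fail_quads
            else "none"
        )
        reads.append(
            CalledRead(
                anchor_id=aid,
                fov_id=int(a.fov_id),
                x_px=int(a.x_px),
                y_px=int(a.y_px),
                seq=seq,
                base_provenance=prov,
                stopped_at_quad=prov[-1][0] if prov else 0,
                excluded_reason=excluded,
            )
        )
    return reads


def filter_reads(
    reads: list[CalledRead],
    min_len: int = 5,
    byproduct_flags: dict[str, bool] | set[str] | None = None,
) -> tuple[list[CalledRead], list[CalledRead]]:
    """Partition reads into (kept, removed).

    Removes reads shorter than ``min_len``, reads excluded upstream (cleave
    failure) and reads flagged as byproducts — either via the read's own
    ``byproduct`` attribute or via ``byproduct_flags`` keyed by read id.
    The partition is exhaustive and disjoint.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    flags = byproduct_flags or {}

    def flagged(r: CalledRead) -> bool:
        if r.byproduct:
            return True
        if isinstance(flags, set):
            return r.read_id in flags
        return bool(flags.get(r.read_id, False))

    kept, removed = [], []
    for r in reads:
        if r.length < min_len or r.excluded_reason != "none" or flagged(r):
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed
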