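"""Virtual-terminator flow chemistry.

Single-molecule sequencing-by-synthesis (smSBS) adds one fluorescent,
reversibly terminating nucleotide (a "virtual terminator", VT) species per
flow.  Four successive flows, one per base, form a *quad*; a run is a fixed
number of quads in a fixed base order (default C, T, A, G).  A molecule
extends by at most one base per flow, and only when the flowed base
complements the next unpaired template base.

This module is purely deterministic: it models flow schedules, the synthesis
track implied by a template construct (what base sequence the polymerase must
add, in order), and the ideal incorporation schedule of a track under a flow
schedule.  Stochastic behaviour (pausing, misincorporation, detachment, ...)
lives in :mod:`smsbs.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "BASES",
    "COMPLEMENT",
    "Flow",
    "FlowSchedule",
    "TemplateConstruct",
    "SynthesisTrack",
    "ReferenceSet",
    "complement",
    "reverse_complement",
    "build_flow_schedule",
    "synthesis_track",
    "expected_schedule",
]

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default flow order within a quad (the order the instrument cycles dyes).
DEFAULT_QUAD_ORDER = "CTAG"


def _validate_seq(seq: str, what: str = "sequence") -> str:
    seq = str(seq)
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(
            f"{what} contains characters outside ACGT: {sorted(bad)!r}"
        )
    return seq


def complement(seq: str) -> str:
    """Base-wise complement (same orientation)."""
    _validate_seq(seq)
    return seq.translate(str.maketrans(COMPLEMENT))


def reverse_complement(seq: str) -> str:
    """Reverse complement, i.e. the complementary strand read 5'→3'."""
    return complement(seq)[::-1]


@dataclass(frozen=True)
class Flow:
    """One nucleotide flow: 1-based quad index, 1-based flow-in-quad, base."""

    quad: int
    flow: int
    base: str


@dataclass(frozen=True)
class FlowSchedule:
    """An ordered list of single-nucleotide flows grouped into quads.

    Parameters
    ----------
    quad_order:
        Permutation of ``ACGT`` giving the within-quad flow order.
    n_quads:
        Number of quads; the schedule has ``4 * n_quads`` flows.
    """

    quad_order: str
    n_quads: int

    def __post_init__(self) -> None:
        order = str(self.quad_order).upper()
        if sorted(order) != sorted(BASES):
            raise ValueError(
                f"quad_order must be a permutation of ACGT, got {self.quad_order!r}"
            )
        if self.n_quads < 0:
            raise ValueError("n_quads must be >= 0")
        object.__setattr__(self, "quad_order", order)

    @property
    def flows(self) -> list[Flow]:
        """Flows enumerated quad-major, then in quad order."""
        return [
            Flow(q, f + 1, base)
            for q in range(1, self.n_quads + 1)
            for f, base in enumerate(self.quad_order)
        ]

    @property
    def n_flows(self) -> int:
        return 4 * self.n_quads

    def __iter__(self) -> Iterator[Flow]:
        return iter(self.flows)

    def to_dict(self) -> dict:
        return {"quad_order": self.quad_order, "n_quads": self.n_quads}


def build_flow_schedule(quad_order: str = DEFAULT_QUAD_ORDER, n_quads: int = 24) -> FlowSchedule:
    """Build a flow schedule of ``n_quads`` quads in ``quad_order``."""
    return FlowSchedule(quad_order=quad_order, n_quads=n_quads)


@dataclass(frozen=True)
class TemplateConstruct:
    """A surface-captured template, restricted to the part that is copied.

    ``template_seq`` is the template 5'→3', i.e. the portion 5' of the
    primer/capture site that the polymerase copies.  In ``polyA_dT`` capture
    the template carries a 3' poly-A tail that the fill step copies with dTTP
    before sequencing starts; in ``specific_primer`` capture a primer
    hybridises directly and no fill occurs.  The lock incorporation (a VT
    added together with the fill so every molecule is imaged once before the
    first cycle) consumes the first sequencing position when
    ``lock_policy="consume_first"``; the lock base is imaged but never called
    because the fill-and-lock mix carries several VT species in one dye
    channel.
    """

    template_seq: str
    capture_mode: str = "polyA_dT"
    lock_policy: str = "consume_first"

    def __post_init__(self) -> None:
        seq = _validate_seq(self.template_seq, "template_seq").upper()
        if not seq:
            raise ValueError("template_seq must be non-empty")
        if self.capture_mode not in ("polyA_dT", "specific_primer"):
            raise ValueError(f"unknown capture_mode {self.capture_mode!r}")
        if self.lock_policy not in ("consume_first", "none"):
            raise ValueError(f"unknown lock_policy {self.lock_policy!r}")
        object.__setattr__(self, "template_seq", seq)


@dataclass(frozen=True)
class SynthesisTrack:
    """The ordered bases the polymerase must incorporate during sequencing.

    ``needed`` is the complement of the template read 3'→5' (synthesis
    order), after removing bases consumed by the fill (the poly-A tail in
    ``polyA_dT`` mode) and by the lock incorporation.  ``lock_base`` records
    the uncalled lock base, if any.
    """

    needed: str
    lock_base: str | None = None


def synthesis_track(template: TemplateConstruct) -> SynthesisTrack:
    """Derive the synthesis track of a template construct.

    The polymerase reads the template 3'→5', so the track is the reverse
    complement of ``template_seq``.  In ``polyA_dT`` mode the 3'-terminal
    A-run (the poly-A tail) is filled with dTTP before imaging and is
    excluded; with ``lock_policy="consume_first"`` the first remaining track
    base is incorporated as the (uncalled) lock.
    """
    seq = template.template_seq
    if template.capture_mode == "polyA_dT":
        seq = seq.rstrip("A")
        if not seq:
            raise ValueError("template is all poly-A; nothing to sequence")
    needed = reverse_complement(seq)
    lock_base = None
    if template.lock_policy == "consume_first":
        lock_base, needed = needed[0], needed[1:]
    return SynthesisTrack(needed=needed, lock_base=lock_base)


def expected_schedule(track: SynthesisTrack, schedule: FlowSchedule) -> list[list[Flow]]:
    """Ideal incorporation schedule of ``track`` under ``schedule``.

    Simulates error-free terminator chemistry: at each flow, exactly one base
    incorporates iff the flow base equals the next needed base.  A homopolymer
    therefore consumes one flow of that base per quad visit.  Returns one list
    of incorporation flows per quad (length ``schedule.n_quads``).
    """
    per_quad: list[list[Flow]] = [[] for _ in range(schedule.n_quads)]
    i = 0
    needed = track.needed
    for fl in schedule:
        if i < len(needed) and fl.base == needed[i]:
            per_quad[fl.quad - 1].append(fl)
            i += 1
    return per_quad


@dataclass
class ReferenceSet:
    """An ordered set of named reference sequences (e.g. a barcode library).

    Sequences are stored in *read orientation*: the orientation in which
    called reads (the synthesized strand) are compared against them.
    """

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {
            str(name): _validate_seq(seq, f"reference {name!r}").upper()
            for name, seq in dict(self.entries).items()
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __getitem__(self, name: str) -> str:
        return self.entries[name]

    def items(self):
        return self.entries.items()

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    @property
    def sequences(self) -> list[str]:
        return list(self.entries.values())

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.entries.values())
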