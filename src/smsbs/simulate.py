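"""Seeded generative model of an smSBS run.

Produces, per field of view (FOV), ground-truth molecules and the per-imaging
-event spot tables a spot detector would emit, with the stochastic behaviours
seen on a real instrument:

* **pause** — a quad in which the matching flow yields no incorporation
  (retried in later quads);
* **dark** — an incorporation that produces no detectable spot (a deletion in
  the called read);
* **misincorporation** — an incorporation at a flow whose base does not match
  the next template base (a substitution or insertion in the read);
* **full stop / detachment** — permanent cessation of extension;
* **cleave failure** — a dye persisting into the post-cleave image (the read
  is later excluded);
* **stage drift** — an integer pixel translation of every spot in an imaging
  event;
* **non-specific spots** — Poisson background spots unrelated to any
  molecule.

Imaging model: one *initial-position* image (the fill-and-lock lock
incorporation, event ``quad 0``), one incorporation-phase image per flow
(4 per quad) and one post-cleave image per quad.  Spot coordinates are
integer pixels (0-based, x = column, y = row, round-half-to-even), matching
the instrument's spot-detection output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .chemistry import (
    BASES,
    FlowSchedule,
    ReferenceSet,
    SynthesisTrack,
    TemplateConstruct,
    build_flow_schedule,
    reverse_complement,
    synthesis_track,
)

__all__ = [
    "DriftModel",
    "RunConfig",
    "FlowEvent",
    "MoleculeTruth",
    "SimulatedRun",
    "SPOT_COLUMNS",
    "imaging_events",
    "make_barcode_library",
    "simulate_run",
    "render_images",
    "detect_spots",
    "ANCHORING_PRESETS",
]

#: Column order of a spot table.
SPOT_COLUMNS = ["fov_id", "quad", "flow", "phase", "x_px", "y_px", "molecule_id"]

#: Per-quad full-stop probabilities standing in for the three anchoring
#: chemistries (covalent NHS, 4×biotin–avidin, 1×biotin–avidin).  Chosen to
#: order mean read lengths NHS > biotin×4 > biotin×1.
ANCHORING_PRESETS = {"nhs": 0.020, "biotin4": 0.035, "biotin1": 0.060}


@dataclass(frozen=True)
class DriftModel:
    """Integer stage-drift model, relative to the initial-position image.

    ``independent`` draws a fresh uniform offset in [-max_abs_px, max_abs_px]
    per imaging event; ``cumulative`` takes a clipped ±1 random-walk step per
    event.  The initial-position image defines the origin (zero drift).
    """

    max_abs_px: int = 4
    walk: str = "independent"

    def __post_init__(self) -> None:
        if self.max_abs_px < 0:
            raise ValueError("max_abs_px must be >= 0")
        if self.walk not in ("independent", "cumulative"):
            raise ValueError(f"unknown drift walk {self.walk!r}")


@dataclass(frozen=True)
class RunConfig:
    """All parameters of a simulated run.

    Probabilities are per the events described in the module docstring:
    ``p_pause`` and ``p_dark`` are per matching-flow decision (their sum must
    be <= 1), ``p_mis`` is the per-quad probability of one misincorporation
    event, ``p_detach`` is per quad, ``p_cleavefail`` per detected
    incorporation.  ``nonspecific_rate`` is the Poisson mean of spurious
    spots per image.  Identical (config, references) pairs yield bit-identical
    outputs.
    """

    n_fovs: int = 4
    fov_size_px: int = 512
    n_quads: int = 24
    quad_order: str = "CTAG"
    density: int = 250
    drift: DriftModel = field(default_factory=DriftModel)
    p_pause: float = 0.10
    p_dark: float = 0.02
    p_mis: float = 0.02
    p_detach: float = 0.04
    p_cleavefail: float = 0.01
    nonspecific_rate: float = 5.0
    capture_mode: str = "polyA_dT"
    lock_policy: str = "consume_first"
    polya_tail: int = 20
    edge_margin_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_pause", "p_dark", "p_mis", "p_detach", "p_cleavefail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_pause + self.p_dark > 1.0:
            raise ValueError("p_pause + p_dark must be <= 1")
        if self.nonspecific_rate < 0:
            raise ValueError("nonspecific_rate must be >= 0")
        if self.density > self.fov_size_px**2:
            raise ValueError("density exceeds one molecule per pixel")
        if not 0 <= 2 * self.edge_margin_px < self.fov_size_px:
            raise ValueError("edge_margin_px must leave a positive placement area")

    @property
    def schedule(self) -> FlowSchedule:
        return build_flow_schedule(self.quad_order, self.n_quads)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drift"] = asdict(self.drift)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("drift"), dict):
            d["drift"] = DriftModel(**d["drift"])
        return cls(**d)


@dataclass(frozen=True)
class FlowEvent:
    """One per-flow fate in a molecule's event log.

    ``fate`` is one of ``incorp``, ``pause``, ``dark``, ``mis_sub``,
    ``mis_ins``, ``detach``.  ``detected`` marks fates that emit an
    incorporation-phase spot; ``cleave_fail`` marks incorporations whose dye
    persists into the quad's post-cleave image.
    """

    quad: int
    flow: int
    base: str
    fate: str
    detected: bool = False
    cleave_fail: bool = False


@dataclass
class MoleculeTruth:
    molecule_id: int
    fov_id: int
    x: float
    y: float
    template: TemplateConstruct
    track: SynthesisTrack
    source_reference_id: str
    event_log: list[FlowEvent] = field(default_factory=list)

    @property
    def true_read(self) -> str:
        """The base sequence a perfect detector/caller would report."""
        return "".join(e.base for e in self.event_log if e.detected)

    @property
    def n_errors_true(self) -> int:
        """Planted errors among detected bases plus dark deletions."""
        return sum(
            1
            for e in self.event_log
            if e.fate in ("mis_sub", "mis_ins", "dark")
        )


@dataclass
class SimulatedRun:
    config: RunConfig
    references: ReferenceSet
    molecules: list[MoleculeTruth]
    spots: pd.DataFrame
    drift: pd.DataFrame  # per (fov_id, quad, flow, phase): dx_px, dy_px

    @property
    def schedule(self) -> FlowSchedule:
        return self.config.schedule


def imaging_events(n_quads: int) -> list[tuple[int, int, str]]:
    """Ordered imaging events of a run: (quad, flow, phase).

    Event (0, 0, 'incorporation') is the initial-position (fill-and-lock)
    image; each quad then contributes four incorporation images and one
    post-cleave image (quad, 0, 'post_cleave').
    """
    events: list[tuple[int, int, str]] = [(0, 0, "incorporation")]
    for q in range(1, n_quads + 1):
        events.extend((q, f, "incorporation") for f in range(1, 5))
        events.append((q, 0, "post_cleave"))
    return events


def make_barcode_library(
    n: int,
    length: int = 25,
    seed: int = 0,
    min_pairwise_hamming: int = 8,
    prefix: str = "B",
) -> ReferenceSet:
    """Generate ``n`` random barcodes with pairwise Hamming distance bounds.

    Rejection sampling with a bounded number of attempts; deterministic per
    seed.  Barcode ids are ``B_01 .. B_n`` by default, mirroring common
    barcode-panel naming.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < min_pairwise_hamming:
        raise ValueError("length must be >= min_pairwise_hamming")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    max_attempts = 1000 * n
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not satisfy min_pairwise_hamming={min_pairwise_hamming} "
                f"after {max_attempts} attempts"
            )
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != a).sum()) >= min_pairwise_hamming for a in accepted):
            accepted.append(cand)
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    width = max(2, len(str(n)))
    entries = {
        f"{prefix}_{i + 1:0{width}d}": lut[a].tobytes().decode()
        for i, a in enumerate(accepted)
    }
    return ReferenceSet(entries)


def _round_px(v: float) -> int:
    # round-half-to-even, the numpy convention
    return int(np.round(v))


def _simulate_chemistry(
    track: SynthesisTrack, config: RunConfig, rng: np.random.Generator
) -> list[FlowEvent]:
    """Walk the flow schedule for one molecule, drawing stochastic fates."""
    needed = track.needed
    order = config.quad_order
    log: list[FlowEvent] = []
    i = 0
    for q in range(1, config.n_quads + 1):
        if rng.random() < config.p_detach:
            log.append(FlowEvent(q, 0, "", "detach"))
            break
        # one potential misincorporation per quad, at a flow whose base does
        # not match the base needed at quad entry
        mis_flow = 0
        if i < len(needed) and rng.random() < config.p_mis:
            others = [f + 1 for f, b in enumerate(order) if b != needed[i]]
            mis_flow = int(rng.choice(others))
        for f, base in enumerate(order, start=1):
            if f == mis_flow:
                fate = "mis_sub" if rng.random() < 0.5 else "mis_ins"
                if fate == "mis_sub":
                    i += 1
                cf = rng.random() < config.p_cleavefail
                log.append(FlowEvent(q, f, base, fate, detected=True, cleave_fail=cf))
                continue
            if i < len(needed) and base == needed[i]:
                u = rng.random()
                if u < config.p_pause:
                    log.append(FlowEvent(q, f, base, "pause"))
                elif u < config.p_pause + config.p_dark:
                    i += 1
                    log.append(FlowEvent(q, f, base, "dark"))
                else:
                    i += 1
                    cf = rng.random() < config.p_cleavefail
                    log.append(
                        FlowEvent(q, f, base, "incorp", detected=True, cleave_fail=cf)
                    )
    return log


def _draw_drift(
    config: RunConfig, events: Sequence[tuple[int, int, str]], rng: np.random.Generator
) -> dict[tuple[int, int, str], tuple[int, int]]:
    m = config.drift.max_abs_px
    offsets: dict[tuple[int, int, str], tuple[int, int]] = {}
    dx = dy = 0
    for ev in events:
        if ev == (0, 0, "incorporation") or m == 0:
            offsets[ev] = (0, 0)
            dx = dy = 0
            continue
        if config.drift.walk == "independent":
            dx = int(rng.integers(-m, m + 1))
            dy = int(rng.integers(-m, m + 1))
        else:  # cumulative clipped random walk
            dx = int(np.clip(dx + rng.integers(-1, 2), -m, m))
            dy = int(np.clip(dy + rng.integers(-1, 2), -m, m))
        offsets[ev] = (dx, dy)
    return offsets


def simulate_run(
    config: RunConfig,
    refs: ReferenceSet,
    weights: Sequence[float] | None = None,
) -> SimulatedRun:
    """Simulate a full run: molecules, event logs and per-event spot tables.

    Molecules are placed uniformly at random per FOV (within
    ``edge_margin_px`` of the border if set — spots of border molecules can
    drift out of frame and are lost) and assigned a reference uniformly.
    Templates carry a poly-A tail (``polyA_dT`` capture) so that the
    synthesis track — hence the error-free read — is the reference sequence
    itself, minus the lock base when ``lock_policy`` consumes it.
    ``weights`` sets relative barcode abundances (default uniform), emulating
    unequal loading stoichiometry.
    """
    if len(refs) == 0:
        raise ValueError("reference set must be non-empty")
    probs = None
    if weights is not None:
        probs = np.asarray(weights, dtype=float)
        if len(probs) != len(refs) or (probs < 0).any() or probs.sum() == 0:
            raise ValueError("weights must be non-negative, one per reference")
        probs = probs / probs.sum()
    rng = np.random.default_rng(config.seed)
    events = imaging_events(config.n_quads)
    ref_names = refs.names

    molecules: list[MoleculeTruth] = []
    rows: list[tuple] = []
    drift_rows: list[tuple] = []
    next_id = 0
    size = config.fov_size_px
    for fov in range(config.n_fovs):
        # placement and reference assignment
        fov_mols: list[MoleculeTruth] = []
        lo, hi = config.edge_margin_px, size - config.edge_margin_px
        for _ in range(config.density):
            x = float(rng.uniform(lo, hi))
            y = float(rng.uniform(lo, hi))
            if probs is None:
                ref_id = ref_names[int(rng.integers(len(ref_names)))]
            else:
                ref_id = ref_names[int(rng.choice(len(ref_names), p=probs))]
            tail = "A" * config.polya_tail if config.capture_mode == "polyA_dT" else ""
            template = TemplateConstruct(
                template_seq=reverse_complement(refs[ref_id]) + tail,
                capture_mode=config.capture_mode,
                lock_policy=config.lock_policy,
            )
            mol = MoleculeTruth(
                molecule_id=next_id,
                fov_id=fov,
                x=x,
                y=y,
                template=template,
                track=synthesis_track(template),
                source_reference_id=ref_id,
            )
            next_id += 1
            fov_mols.append(mol)
        detected_at: dict[tuple[int, int], list[MoleculeTruth]] = {}
        cleavefail_at: dict[int, list[MoleculeTruth]] = {}
        for mol in fov_mols:
            mol.event_log = _simulate_chemistry(mol.track, config, rng)
            for e in mol.event_log:
                if e.detected:
                    detected_at.setdefault((e.quad, e.flow), []).append(mol)
                if e.cleave_fail:
                    cf = cleavefail_at.setdefault(e.quad, [])
                    if not cf or cf[-1] is not mol:
                        cf.append(mol)
        offsets = _draw_drift(config, events, rng)

        # spot emission, in event order
        for ev in events:
            q, f, phase = ev
            dx, dy = offsets[ev]
            if ev == (0, 0, "incorporation"):
                # lock incorporation: every molecule is visible
                for mol in fov_mols:
                    xi, yi = _round_px(mol.x), _round_px(mol.y)
                    if 0 <= xi < size and 0 <= yi < size:
                        rows.append((fov, 0, 0, phase, xi, yi, mol.molecule_id))
            elif phase == "incorporation":
                for mol in detected_at.get((q, f), ()):
                    xi = _round_px(mol.x + dx)
                    yi = _round_px(mol.y + dy)
                    if 0 <= xi < size and 0 <= yi < size:
                        rows.append((fov, q, f, phase, xi, yi, mol.molecule_id))
            else:  # post-cleave image: only cleave-failed dyes persist
                for mol in cleavefail_at.get(q, ()):
                    xi = _round_px(mol.x + dx)
                    yi = _round_px(mol.y + dy)
                    if 0 <= xi < size and 0 <= yi < size:
                        rows.append((fov, q, 0, phase, xi, yi, mol.molecule_id))
            n_ns = int(rng.poisson(config.nonspecific_rate))
            for _ in range(n_ns):
                rows.append(
                    (
                        fov,
                        q,
                        f,
                        phase,
                        int(rng.integers(size)),
                        int(rng.integers(size)),
                        -1,
                    )
                )
            drift_rows.append((fov, q, f, phase, dx, dy))
        molecules.extend(fov_mols)

    spots = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    drift = pd.DataFrame(
        drift_rows, columns=["fov_id", "quad", "flow", "phase", "dx_px", "dy_px"]
    )
    return SimulatedRun(
        config=config, references=refs, molecules=molecules, spots=spots, drift=drift
    )


# ---------------------------------------------------------------------------
# image rendering / stand-in spot detection (demo and detector-parity checks)
# ---------------------------------------------------------------------------

def render_images(
    spots: pd.DataFrame,
    fov_size_px: int,
    psf_sigma_px: float = 1.2,
    snr: float = 20.0,
    background: float = 100.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> dict[tuple[int, int, int, str], np.ndarray]:
    """Render one image per imaging event present in ``spots``.

    Each spot is an isotropic Gaussian of amplitude ``snr * noise_sd`` on a
    noisy background.  Returns a dict keyed by (fov_id, quad, flow, phase).
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    rng = np.random.default_rng(seed)
    out: dict[tuple[int, int, int, str], np.ndarray] = {}
    size = fov_size_px
    yy, xx = np.mgrid[0:size, 0:size]
    keys = (
        spots[["fov_id", "quad", "flow", "phase"]].drop_duplicates().itertuples(index=False)
        if len(spots)
        else []
    )
    for key in keys:
        key = tuple(key)
        img = background + rng.normal(0.0, noise_sd, size=(size, size))
        sel = spots[
            (spots.fov_id == key[0])
            & (spots.quad == key[1])
            & (spots.flow == key[2])
            & (spots.phase == key[3])
        ]
        amp = snr * noise_sd
        for _, s in sel.iterrows():
            r2 = (xx - s.x_px) ** 2 + (yy - s.y_px) ** 2
            img += amp * np.exp(-r2 / (2 * psf_sigma_px**2))
        out[key] = img
    return out


def detect_spots(
    image: np.ndarray, threshold_sigma: float = 5.0, min_separation_px: int = 3
) -> pd.DataFrame:
    """Stand-in spot detector: thresholded local maxima on a single image.

    Background and noise s.d. are estimated robustly (median / MAD); local
    maxima above ``background + threshold_sigma * sd`` are kept with
    non-maximum suppression within ``min_separation_px``, and reported as
    integer pixel coordinates (x = column, y = row).
    """
    from skimage.feature import peak_local_max

    image = np.asarray(image, dtype=float)
    bg = float(np.median(image))
    sd = 1.4826 * float(np.median(np.abs(image - bg)))
    if sd == 0:
        sd = float(image.std()) or 1.0
    peaks = peak_local_max(
        image,
        min_distance=min_separation_px,
        threshold_abs=bg + threshold_sigma * sd,
        exclude_border=False,
    )
    return pd.DataFrame(
        {"x_px": peaks[:, 1].astype(int), "y_px": peaks[:, 0].astype(int)}
    )
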