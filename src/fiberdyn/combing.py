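"""Observation model: from an ideal labeled molecule to combed-fiber data.

Molecular combing stretches genomic DNA uniformly on silanised glass, so
lengths measured in μm convert linearly to kb (default 2 kb per μm).  The
molecule arrives on the slide fragmented into finite fibers; labeled segments
are clipped at fragmentation breakpoints (and flagged censored there), and
segments below the optical detection limit drop out.  A deliberately toy
two-channel image renderer / track extractor provides an inverse-consistency
check of the measurement chain; real-slide artefacts (crossing fibers,
breaks, uneven stretching) are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .distributions import SpecError
from .repsim import CLDU, IDU, UNLABELED, LabeledMolecule, Scenario, Segment

__all__ = [
    "UnitConversion",
    "Fiber",
    "kb_to_um",
    "um_to_kb",
    "fragment_into_fibers",
    "render_fiber_image",
    "extract_tracks_from_image",
]


@dataclass(frozen=True)
class UnitConversion:
    """Linear combing stretch factor: 1 μm of fiber ≈ ``kb_per_um`` kb."""

    kb_per_um: float = 2.0

    def __post_init__(self) -> None:
        if self.kb_per_um <= 0:
            raise SpecError("kb_per_um must be > 0")


def kb_to_um(length_kb: float, conv: UnitConversion = UnitConversion()) -> float:
    if length_kb < 0:
        raise SpecError("length must be >= 0")
    return length_kb / conv.kb_per_um


def um_to_kb(length_um: float, conv: UnitConversion = UnitConversion()) -> float:
    if length_um < 0:
        raise SpecError("length must be >= 0")
    return length_um * conv.kb_per_um


@dataclass
class Fiber:
    """One combed fragment: labeled segments in fiber-local kb coordinates.

    ``left_censored`` / ``right_censored`` flag terminal segments that abut a
    fragmentation breakpoint (the structure continued on another fragment).
    """

    fiber_id: str
    length: float
    segments: list[Segment]
    left_censored: bool = False
    right_censored: bool = False
    ground_truth: dict = field(default_factory=dict)

    def check_invariants(self, atol: float = 1e-9) -> None:
        pos = 0.0
        prev = None
        for seg in self.segments:
            if abs(seg.start - pos) > atol or seg.end <= seg.start:
                raise AssertionError("fiber segments must tile [0, length)")
            if prev is not None and seg.label == prev:
                raise AssertionError("adjacent fiber segments share a label")
            prev, pos = seg.label, seg.end
        if abs(pos - self.length) > atol:
            raise AssertionError("fiber segments must cover the fiber")


def _clip_segments(segments: list[Segment], lo: float, hi: float) -> list[Segment]:
    out = []
    for seg in segments:
        s, e = max(seg.start, lo), min(seg.end, hi)
        if e - s > 1e-12:
            out.append(Segment(seg.label, s - lo, e - lo))
    return out


def apply_detection_limit(segments: list[Segment], limit: float) -> list[Segment]:
    """Labeled segments shorter than ``limit`` drop out as unlabeled.

    Dropped slivers merge into flanking unlabeled spans; they never bridge two
    like-labeled neighbours into one longer track (conservative reading of an
    optical dropout)."""
    relabeled = [
        Segment(UNLABELED, s.start, s.end)
        if s.label != UNLABELED and s.length < limit
        else s
        for s in segments
    ]
    out: list[Segment] = []
    for seg in relabeled:
        if out and out[-1].label == seg.label:
            out[-1] = Segment(seg.label, out[-1].start, seg.end)
        else:
            out.append(seg)
    return out


def fragment_into_fibers(
    molecule: LabeledMolecule,
    scenario: Scenario,
    rng: np.random.Generator,
    molecule_index: int = 0,
    fiber_length_mean: float | None = None,
) -> list[Fiber]:
    """Cut a molecule at renewal breakpoints into finite combed fibers.

    ``fiber_length_mean`` optionally overrides the scenario's configured mean
    (e.g. long-fiber preparations for interorigin-distance measurements).
    """
    spec = scenario.fiber_length
    if fiber_length_mean is not None:
        from dataclasses import replace

        spec = replace(spec, mean=fiber_length_mean)
    if spec.expectation <= scenario.detection_limit:
        raise SpecError("fiber length mean must exceed the detection limit")

    L = molecule.region_length
    cuts: list[float] = []
    x = rng.uniform(0.0, spec.sample_one(rng))
    while x < L:
        cuts.append(x)
        x += spec.sample_one(rng)
    bounds = [0.0] + cuts + [L]

    origin_positions = [o.position for o in molecule.ground_truth.origins]
    fibers: list[Fiber] = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if hi - lo <= 1e-9:
            continue
        segs = _clip_segments(molecule.segments, lo, hi)
        segs = apply_detection_limit(segs, scenario.detection_limit)
        fiber = Fiber(
            fiber_id=f"m{molecule_index}_f{k}",
            length=hi - lo,
            segments=segs,
            left_censored=lo > 0.0,
            right_censored=hi < L,
            ground_truth={
                "molecule_index": molecule_index,
                "offset": lo,
                "origins": [p - lo for p in origin_positions if lo <= p < hi],
            },
        )
        fiber.check_invariants()
        fibers.append(fiber)
    return fibers


# ----------------------------------------------------------------------
# Toy image renderer / extractor
# ----------------------------------------------------------------------
_CHANNELS = {IDU: 0, CLDU: 1}


def render_fiber_image(
    fiber: Fiber,
    pixel_size: float = 0.2,
    psf_sigma: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    conv: UnitConversion = UnitConversion(),
    height: int = 9,
    margin: int = 4,
) -> np.ndarray:
    """Render a fiber as a 2×H×W raster (channel 0 IdU, channel 1 CldU).

    The fiber lies horizontally as a 3-px band; labels paint unit intensity
    into their channel, then Gaussian blur and additive noise are applied.
    """
    if pixel_size <= 0:
        raise SpecError("pixel_size must be > 0")
    width = int(np.ceil(kb_to_um(fiber.length, conv) / pixel_size)) + 2 * margin
    img = np.zeros((2, height, width))
    band = slice(height // 2 - 1, height // 2 + 2)
    for seg in fiber.segments:
        if seg.label == UNLABELED:
            continue
        c0 = margin + kb_to_um(seg.start, conv) / pixel_size
        c1 = margin + kb_to_um(seg.end, conv) / pixel_size
        img[_CHANNELS[seg.label], band, int(round(c0)) : int(round(c1))] = 1.0
    if psf_sigma > 0:
        for ch in range(2):
            img[ch] = gaussian_filter(img[ch], psf_sigma)
    if noise_sd > 0:
        if rng is None:
            raise SpecError("noise_sd > 0 requires an rng")
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


def extract_tracks_from_image(
    image: np.ndarray,
    pixel_size: float = 0.2,
    conv: UnitConversion = UnitConversion(),
    threshold: float = 0.4,
) -> Fiber:
    """Recover labeled segments from a rendered fiber image.

    Per-channel maximum-intensity profiles along the fiber axis are
    thresholded and run-length encoded into segments; pixel runs convert back
    to kb through the combing stretch factor."""
    prof = image.max(axis=1)  # (2, W)
    width = prof.shape[1]
    above = prof > threshold
    if not above.any():
        warnings.warn("no fiber detected in image", stacklevel=2)
        length = um_to_kb(width * pixel_size, conv)
        return Fiber("extracted", length, [Segment(UNLABELED, 0.0, length)])
    labels = np.full(width, UNLABELED, dtype=object)
    idu_wins = above[0] & (prof[0] >= prof[1])
    cldu_wins = above[1] & (prof[1] > prof[0])
    labels[idu_wins] = IDU
    labels[cldu_wins] = CLDU

    length = um_to_kb(width * pixel_size, conv)
    segments: list[Segment] = []
    run_start = 0
    for i in range(1, width + 1):
        if i == width or labels[i] != labels[run_start]:
            s = um_to_kb(run_start * pixel_size, conv)
            e = um_to_kb(i * pixel_size, conv) if i < width else length
            segments.append(Segment(str(labels[run_start]), s, e))
            run_start = i
    fiber = Fiber("extracted", length, segments)
    fiber.check_invariants()
    return fiber
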