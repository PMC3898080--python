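"""Stochastic forward simulator of DNA replication with dual-pulse labeling.

The model: replication origins are placed along a genomic region as a renewal
process (i.i.d. gaps), each origin fires at a random time and launches a left
and a right fork.  Sister forks share a per-replicon velocity plus independent
Gaussian noise; each fork may permanently stall (per-minute Bernoulli hazard,
evaluated on a 1-minute grid) and converging forks from adjacent origins
terminate where they meet.  Fork kinematics between events are exact (linear),
so label boundaries carry no discretisation error.

DNA synthesised during the first analog pulse is labeled ``IdU``, during the
second ``CldU``; DNA made before the pulses (or never made) is unlabeled.
Coordinates are kb, 0-based, half-open intervals throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .distributions import DistributionSpec, SpecError

__all__ = [
    "PulseScheme",
    "Scenario",
    "Origin",
    "Fork",
    "Segment",
    "GroundTruth",
    "LabeledMolecule",
    "sample_origins",
    "simulate_replication",
    "simulate_molecules",
    "replicated_fraction",
]

IDU = "IdU"
CLDU = "CldU"
UNLABELED = "unlabeled"


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PulseScheme:
    """Two contiguous analog pulses; times in minutes on the simulation clock."""

    pulse1_label: str = IDU
    pulse1_duration: float = 20.0
    pulse2_label: str = CLDU
    pulse2_duration: float = 20.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.pulse1_duration <= 0 or self.pulse2_duration <= 0:
            raise SpecError("pulse durations must be > 0")

    @property
    def t0(self) -> float:
        return self.start_time

    @property
    def t1(self) -> float:
        """Pulse-1/pulse-2 boundary (pulses are contiguous)."""
        return self.start_time + self.pulse1_duration

    @property
    def t2(self) -> float:
        return self.t1 + self.pulse2_duration


@dataclass(frozen=True)
class Scenario:
    """Full parameterisation of one genotype/condition."""

    name: str
    region_length: float  # kb
    origin_spacing: DistributionSpec  # kb
    firing_time: DistributionSpec  # minutes, relative to pulse clock
    fork_velocity: DistributionSpec  # kb/min, drawn per replicon
    sister_noise_sd: float = 0.0  # kb/min, independent per fork
    stall_rate: float = 0.0  # per-fork per-minute probability
    pulses: PulseScheme = field(default_factory=PulseScheme)
    fiber_length: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("lognormal", mean=500.0, sigma_log=0.5)
    )
    detection_limit: float = 1.0  # kb, smallest reportable labeled segment
    kb_per_um: float = 2.0
    n_molecules: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length <= 0:
            raise SpecError("region_length must be > 0")
        if self.origin_spacing.expectation <= 0:
            raise SpecError("origin spacing mean must be > 0")
        if self.fork_velocity.expectation <= 0:
            raise SpecError("mean fork velocity must be > 0")
        if not 0.0 <= self.stall_rate <= 1.0:
            raise SpecError("stall_rate must be in [0, 1]")
        if self.sister_noise_sd < 0:
            raise SpecError("sister_noise_sd must be >= 0")
        if self.detection_limit < 0:
            raise SpecError("detection_limit must be >= 0")
        if self.kb_per_um <= 0:
            raise SpecError("kb_per_um must be > 0")
        if self.fiber_length.expectation <= self.detection_limit:
            raise SpecError("fiber length mean must exceed the detection limit")
        if self.n_molecules < 1:
            raise SpecError("n_molecules must be >= 1")


@dataclass(frozen=True)
class Origin:
    position: float  # kb
    firing_time: float  # minutes
    replicon_velocity: float  # kb/min


@dataclass
class Fork:
    origin_index: int
    direction: str  # "left" | "right"
    velocity: float  # kb/min
    firing_time: float
    start_position: float
    stall_time: float | None = None  # absolute minutes, None if never stalls
    termination_time: float | None = None
    termination_position: float | None = None
    end_time: float = math.nan  # when synthesis actually stopped
    end_position: float = math.nan

    @property
    def travel(self) -> float:
        return abs(self.end_position - self.start_position)

    @property
    def stalled(self) -> bool:
        """Arrested by stalling (not by meeting a converging fork)."""
        return self.stall_time is not None and self.termination_time is None


@dataclass(frozen=True)
class Segment:
    label: str
    start: float
    end: float

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class GroundTruth:
    origins: list[Origin]
    forks: list[Fork]


@dataclass
class LabeledMolecule:
    """A genomic region as an ordered list of labeled segments + ground truth.

    Segments tile ``[0, region_length)`` without overlap; adjacent segments
    carry distinct labels.
    """

    region_length: float
    segments: list[Segment]
    ground_truth: GroundTruth

    def check_invariants(self, atol: float = 1e-9) -> None:
        pos = 0.0
        prev = None
        for seg in self.segments:
            if abs(seg.start - pos) > atol:
                raise AssertionError("segments do not tile the region")
            if seg.end <= seg.start:
                raise AssertionError("empty or inverted segment")
            if prev is not None and seg.label == prev:
                raise AssertionError("adjacent segments share a label")
            prev = seg.label
            pos = seg.end
        if abs(pos - self.region_length) > atol:
            raise AssertionError("segments do not cover the region")


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------
def sample_origins(scenario: Scenario, rng: np.random.Generator) -> list[Origin]:
    """Place origins as a renewal process and draw firing times / velocities.

    The first origin sits at a uniform phase offset inside the first renewal
    gap; subsequent gaps are i.i.d. from the configured spacing distribution.
    """
    L = scenario.region_length
    spacing = scenario.origin_spacing
    positions: list[float] = []
    first_gap = spacing.sample_one(rng)
    x = rng.uniform(0.0, first_gap)
    while x < L:
        positions.append(x)
        x += spacing.sample_one(rng)
    n = len(positions)
    firing = scenario.firing_time.sample(rng, n)
    vel = _positive_samples(scenario.fork_velocity, rng, n)
    return [Origin(p, float(f), float(v)) for p, f, v in zip(positions, firing, vel)]


def _positive_samples(spec: DistributionSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample with rejection of non-positive draws (velocities must be > 0)."""
    out = spec.sample(rng, n)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = spec.sample(rng, int(bad.sum()))
    raise SpecError("velocity distribution produces non-positive values")


def _fork_position(fork_x0: float, direction: int, v: float, f: float, cap: float, t: float) -> float:
    dt = min(max(t - f, 0.0), cap - f) if cap > f else 0.0
    return fork_x0 + direction * v * dt


def _meeting_time(
    a_x0: float, a_v: float, a_f: float, a_cap: float,
    b_x0: float, b_v: float, b_f: float, b_cap: float,
    t_end: float,
) -> tuple[float, float] | None:
    """Earliest time <= t_end at which a right-moving fork A meets a
    left-moving fork B, honouring each fork's arrest cap.  Returns (t, x)."""
    breaks = sorted({a_f, b_f, a_cap, b_cap, t_end})
    breaks = [t for t in breaks if t <= t_end]
    if breaks[-1] < t_end:
        breaks.append(t_end)
    t_prev = breaks[0]

    def gap(t: float) -> float:
        xa = _fork_position(a_x0, +1, a_v, a_f, min(a_cap, t_end), t)
        xb = _fork_position(b_x0, -1, b_v, b_f, min(b_cap, t_end), t)
        return xb - xa

    g_prev = gap(t_prev)
    if g_prev <= 0:
        return t_prev, _fork_position(a_x0, +1, a_v, a_f, min(a_cap, t_end), t_prev)
    for t_next in breaks[1:]:
        g_next = gap(t_next)
        if g_next <= 0:
            # linear within the interval
            frac = g_prev / (g_prev - g_next)
            t_star = t_prev + frac * (t_next - t_prev)
            x_star = _fork_position(a_x0, +1, a_v, a_f, min(a_cap, t_end), t_star)
            return t_star, x_star
        t_prev, g_prev = t_next, g_next
    return None


def simulate_replication(
    origins: list[Origin], scenario: Scenario, rng: np.random.Generator
) -> LabeledMolecule:
    """Run fork kinematics and pulse labeling for one molecule."""
    L = scenario.region_length
    p = scenario.pulses
    t_end = p.t2
    n = len(origins)
    if any(origins[i].position > origins[i + 1].position for i in range(n - 1)):
        raise SpecError("origins must be sorted by position")

    # deterministic draw order: all sister noise, then all stall horizons
    noise = (
        rng.normal(0.0, scenario.sister_noise_sd, 2 * n)
        if scenario.sister_noise_sd > 0
        else np.zeros(2 * n)
    )
    if scenario.stall_rate >= 1.0:
        stall_minutes = np.ones(2 * n)
    elif scenario.stall_rate > 0:
        stall_minutes = rng.geometric(scenario.stall_rate, 2 * n).astype(float)
    else:
        stall_minutes = np.full(2 * n, np.inf)

    forks: list[Fork] = []
    for i, o in enumerate(origins):
        for j, direction in enumerate(("left", "right")):
            v = o.replicon_velocity + noise[2 * i + j]
            if v <= 0:  # truncate pathological noise draws
                v = max(o.replicon_velocity * 0.01, 1e-6)
            sm = stall_minutes[2 * i + j]
            stall_t = o.firing_time + sm if np.isfinite(sm) else None
            forks.append(
                Fork(
                    origin_index=i,
                    direction=direction,
                    velocity=float(v),
                    firing_time=o.firing_time,
                    start_position=o.position,
                    stall_time=stall_t if (stall_t is not None and stall_t < t_end) else None,
                )
            )

    def cap_time(fk: Fork) -> float:
        return fk.stall_time if fk.stall_time is not None else t_end

    # converging forks of adjacent origins
    for i in range(n - 1):
        a = forks[2 * i + 1]  # right fork of origin i
        b = forks[2 * (i + 1)]  # left fork of origin i+1
        met = _meeting_time(
            a.start_position, a.velocity, a.firing_time, cap_time(a),
            b.start_position, b.velocity, b.firing_time, cap_time(b),
            t_end,
        )
        if met is not None:
            t_star, x_star = met
            for fk in (a, b):
                fk.termination_time = t_star
                fk.termination_position = x_star
                if fk.stall_time is not None and fk.stall_time <= t_star:
                    # arrested first; the neighbour ran into the arrested tip
                    fk.termination_time = t_star
            # forks arrested before the meeting keep their stall, but the
            # junction still closes at t_star
    # region boundaries clamp the outermost forks
    if n:
        lf = forks[0]
        t_hit = lf.firing_time + lf.start_position / lf.velocity
        if t_hit < min(cap_time(lf), t_end) and (lf.termination_time is None):
            lf.termination_time = t_hit
            lf.termination_position = 0.0
        rf = forks[-1]
        t_hit = rf.firing_time + (L - rf.start_position) / rf.velocity
        if t_hit < min(cap_time(rf), t_end) and (rf.termination_time is None):
            rf.termination_time = t_hit
            rf.termination_position = L

    # resolve each fork's effective stop
    for fk in forks:
        stop = t_end
        if fk.stall_time is not None:
            stop = min(stop, fk.stall_time)
        if fk.termination_time is not None:
            stop = min(stop, fk.termination_time)
        fk.end_time = stop
        if fk.termination_time is not None and stop == fk.termination_time:
            # both converging forks stop exactly at the recorded junction, so
            # their label tracks abut without a floating-point gap
            fk.end_position = fk.termination_position
        else:
            d = +1 if fk.direction == "right" else -1
            dt = max(stop - fk.firing_time, 0.0)
            fk.end_position = min(max(fk.start_position + d * fk.velocity * dt, 0.0), L)

    # label synthesis intervals
    labeled: list[tuple[float, float, str]] = []
    for fk in forks:
        d = +1 if fk.direction == "right" else -1
        for lo_t, hi_t, label in (
            (p.t0, p.t1, p.pulse1_label),
            (p.t1, p.t2, p.pulse2_label),
        ):
            u0 = max(fk.firing_time, lo_t)
            u1 = min(fk.end_time, hi_t)
            if u1 <= u0:
                continue
            x0 = fk.start_position + d * fk.velocity * (u0 - fk.firing_time)
            x1 = fk.start_position + d * fk.velocity * (u1 - fk.firing_time)
            lo, hi = sorted((x0, x1))
            lo, hi = max(lo, 0.0), min(hi, L)
            if hi > lo:
                labeled.append((lo, hi, label))

    labeled.sort(key=lambda s: s[0])
    segments: list[Segment] = []
    pos = 0.0
    for lo, hi, label in labeled:
        lo = max(lo, pos)  # guard against fp-overlap at junctions
        if hi <= lo:
            continue
        if lo - pos > 1e-9:
            segments.append(Segment(UNLABELED, pos, lo))
        else:
            lo = pos
        segments.append(Segment(label, lo, hi))
        pos = hi
    if pos < L:
        segments.append(Segment(UNLABELED, pos, L))
    segments = _merge_adjacent(segments)

    mol = LabeledMolecule(L, segments, GroundTruth(list(origins), forks))
    mol.check_invariants()
    return mol


def _merge_adjacent(segments: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segments:
        if seg.end - seg.start <= 1e-12:
            continue
        if out and out[-1].label == seg.label:
            out[-1] = Segment(seg.label, out[-1].start, seg.end)
        else:
            out.append(seg)
    return out


def replicated_fraction(molecule: LabeledMolecule) -> float:
    """Fraction of the region replicated by simulation end.

    Equals total fork travel over region length (converging forks terminate at
    their meeting point, so travels never double-count)."""
    total = sum(fk.travel for fk in molecule.ground_truth.forks)
    return min(total / molecule.region_length, 1.0)


def simulate_molecules(
    scenario: Scenario, rng: np.random.Generator, n_molecules: int | None = None
) -> list[LabeledMolecule]:
    """Simulate ``n_molecules`` independent labeled regions."""
    n = scenario.n_molecules if n_molecules is None else n_molecules
    out = []
    for _ in range(n):
        origins = sample_origins(scenario, rng)
        out.append(simulate_replication(origins, scenario, rng))
    return out
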