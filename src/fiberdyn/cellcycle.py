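"""Asynchronous cell-cycle population simulator and FACS-style statistics.

Models an exponentially growing (or uniform-age) population of cells whose
G1, S and G2/M durations are drawn per cell from configurable distributions.
In steady exponential growth the stationary age density for a cell with total
cycle length Tc is proportional to 2^(-a/Tc) on [0, Tc); young cells are
over-represented because every division injects two newborns.

From a sampled population the module produces the readouts of time-lapse and
flow-cytometry experiments: anaphase-to-anaphase cycle durations, DNA-content
histograms with G1/S/G2 gates (2N..4N arbitrary units, linear through S, with
multiplicative measurement noise), the BrdU-positive fraction after a short
pulse, and the labeled/unlabeled-G1 ratio over a chase (cells progress
deterministically through their phases and divide; both daughters inherit the
label — analog dilution is ignored over a 24 hr chase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distributions import DistributionSpec, SpecError

__all__ = [
    "CellCycleConfig",
    "CellRecord",
    "ChaseRatioSeries",
    "DurationSample",
    "sample_population",
    "dna_content",
    "dna_content_histogram",
    "brdu_pulse_chase",
    "time_lapse_durations",
    "expected_phase_fractions",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class CellCycleConfig:
    """Phase-duration distributions (minutes) and measurement parameters."""

    name: str
    g1: DistributionSpec
    s: DistributionSpec
    g2m: DistributionSpec
    growth: str = "exponential"  # "exponential" | "uniform"
    dna_noise_cv: float = 0.05
    gate_halfwidth: float = 0.05  # relative, at zero noise; widened by 2 noise sd
    seed: int = 0

    def __post_init__(self) -> None:
        for spec in (self.g1, self.s, self.g2m):
            if spec.expectation <= 0:
                raise SpecError("phase duration means must be > 0")
        if self.growth not in {"exponential", "uniform"}:
            raise SpecError("growth must be 'exponential' or 'uniform'")
        if self.dna_noise_cv < 0:
            raise SpecError("dna_noise_cv must be >= 0")
        lo, hi = self.g1_gate_upper, self.g2_gate_lower
        if not lo < hi:
            raise SpecError("G1 and G2 gates overlap; reduce noise or gate width")

    @property
    def _gate_rel(self) -> float:
        return self.gate_halfwidth + 2.0 * self.dna_noise_cv

    @property
    def g1_gate_upper(self) -> float:
        return 2.0 * (1.0 + self._gate_rel)

    @property
    def g2_gate_lower(self) -> float:
        return 4.0 * (1.0 - self._gate_rel)


@dataclass
class CellRecord:
    g1: float
    s: float
    g2m: float
    age: float  # minutes since last division, at observation time 0
    brdu_labeled: bool = False

    @property
    def tc(self) -> float:
        return self.g1 + self.s + self.g2m

    @property
    def birth_time(self) -> float:
        return -self.age

    @property
    def phase(self) -> str:
        return phase_at_age(self, self.age)


def phase_at_age(cell: CellRecord, age: float) -> str:
    if age < cell.g1:
        return "G1"
    if age < cell.g1 + cell.s:
        return "S"
    return "G2M"


def dna_content(cell: CellRecord, age: float | None = None) -> float:
    """Noiseless DNA content in N units: 2 in G1, linear 2->4 across S, 4 in G2/M."""
    a = cell.age if age is None else age
    if a < cell.g1:
        return 2.0
    if a < cell.g1 + cell.s:
        return 2.0 + 2.0 * (a - cell.g1) / cell.s
    return 4.0


# ----------------------------------------------------------------------
def _sample_age(tc: np.ndarray, growth: str, rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(0.0, 1.0, tc.size)
    if growth == "uniform":
        return u * tc
    # inverse CDF of the stationary age density f(a) = (2 ln2 / Tc) 2^(-a/Tc)
    return -tc * np.log1p(-0.5 * u) / _LN2


def sample_population(
    config: CellCycleConfig, n: int, rng: np.random.Generator
) -> list[CellRecord]:
    """Draw ``n`` cells from the asynchronous steady-state population."""
    if n < 1:
        raise SpecError("population size must be >= 1")
    g1 = config.g1.sample(rng, n)
    s = config.s.sample(rng, n)
    g2m = config.g2m.sample(rng, n)
    if (g1 <= 0).any() or (s <= 0).any() or (g2m <= 0).any():
        raise SpecError("phase durations must be > 0; check distribution families")
    ages = _sample_age(g1 + s + g2m, config.growth, rng)
    return [CellRecord(float(a), float(b), float(c), float(d))
            for a, b, c, d in zip(g1, s, g2m, ages)]


def dna_content_histogram(
    population: list[CellRecord],
    config: CellCycleConfig,
    rng: np.random.Generator | None = None,
) -> dict:
    """Gate a population on (noisy) DNA content; returns fractions and contents."""
    if not population:
        raise SpecError("population must be nonempty")
    content = np.array([dna_content(c) for c in population])
    if config.dna_noise_cv > 0:
        if rng is None:
            raise SpecError("dna_noise_cv > 0 requires an rng")
        content = content * (1.0 + rng.normal(0.0, config.dna_noise_cv, content.size))
    g1 = content <= config.g1_gate_upper
    g2 = content >= config.g2_gate_lower
    s = ~g1 & ~g2
    n = content.size
    return {
        "G1": float(g1.sum() / n),
        "S": float(s.sum() / n),
        "G2": float(g2.sum() / n),
        "contents": content,
    }


def expected_phase_fractions(g1: float, s: float, g2m: float) -> dict[str, float]:
    """Closed-form gate fractions for deterministic durations under
    exponential growth (integral of the stationary age density)."""
    tc = g1 + s + g2m
    F = lambda a: 2.0 * (1.0 - 2.0 ** (-a / tc))  # noqa: E731  CDF of age
    return {"G1": F(g1), "S": F(g1 + s) - F(g1), "G2": 1.0 - F(g1 + s)}


# ----------------------------------------------------------------------
@dataclass
class ChaseRatioSeries:
    times_hr: np.ndarray
    ratio: np.ndarray  # labeled G1 / unlabeled G1 per timepoint
    brdu_positive_fraction: float  # at end of pulse (t = 0)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_hr) <= 0):
            raise SpecError("chase timepoints must be strictly increasing")
        if np.any(self.ratio < 0):
            raise SpecError("ratios must be >= 0")


@dataclass
class _Lineage:
    birth: float
    g1: float
    s: float
    g2m: float
    labeled: bool

    @property
    def division(self) -> float:
        return self.birth + self.g1 + self.s + self.g2m


def brdu_pulse_chase(
    config: CellCycleConfig,
    n: int,
    pulse_duration: float,
    chase_times_hr: list[float],
    rng: np.random.Generator,
) -> ChaseRatioSeries:
    """Label S-phase cells during a pulse, then follow the G1 label ratio.

    The pulse occupies ``[-pulse_duration, 0]`` minutes; a cell is labeled iff
    any part of its S phase overlaps that window.  During the chase cells
    advance deterministically and divide; both daughters inherit the label and
    restart at age zero with freshly drawn phase durations.
    """
    if pulse_duration <= 0:
        raise SpecError("pulse_duration must be > 0")
    if pulse_duration >= config.s.expectation:
        raise SpecError("pulse must be shorter than the mean S phase")
    times = np.asarray(sorted(chase_times_hr), dtype=float)
    max_t = float(times.max()) * 60.0 if times.size else 0.0

    population = sample_population(config, n, rng)
    cells: list[_Lineage] = []
    n_labeled0 = 0
    for c in population:
        s_start, s_end = -c.age + c.g1, -c.age + c.g1 + c.s
        labeled = (s_start < 0.0) and (s_end > -pulse_duration)
        n_labeled0 += labeled
        cells.append(_Lineage(birth=-c.age, g1=c.g1, s=c.s, g2m=c.g2m, labeled=labeled))

    # expand lineages through divisions up to the last chase time
    i = 0
    while i < len(cells):
        cell = cells[i]
        if cell.division <= max_t:
            for _ in range(2):
                cells.append(
                    _Lineage(
                        birth=cell.division,
                        g1=config.g1.sample_one(rng),
                        s=config.s.sample_one(rng),
                        g2m=config.g2m.sample_one(rng),
                        labeled=cell.labeled,
                    )
                )
        i += 1

    ratios = []
    for t_hr in times:
        t = t_hr * 60.0
        lab = unlab = 0
        for cell in cells:
            age = t - cell.birth
            if age < 0 or t >= cell.division:
                continue  # not yet born / already divided at t
            rec = CellRecord(cell.g1, cell.s, cell.g2m, age)
            content = dna_content(rec)
            if config.dna_noise_cv > 0:
                content *= 1.0 + rng.normal(0.0, config.dna_noise_cv)
            if content <= config.g1_gate_upper:
                if cell.labeled:
                    lab += 1
                else:
                    unlab += 1
        ratios.append(lab / unlab if unlab else math.inf)
    return ChaseRatioSeries(
        times_hr=times,
        ratio=np.asarray(ratios),
        brdu_positive_fraction=n_labeled0 / n,
    )


@dataclass
class DurationSample:
    durations: np.ndarray  # minutes, anaphase-to-anaphase
    mean: float
    sd: float

    @property
    def n(self) -> int:
        return int(self.durations.size)


def time_lapse_durations(
    config: CellCycleConfig, n: int, rng: np.random.Generator
) -> DurationSample:
    """Total cycle durations of ``n`` tracked cells (default use: n = 50)."""
    if n < 1:
        raise SpecError("n must be >= 1")
    total = config.g1.sample(rng, n) + config.s.sample(rng, n) + config.g2m.sample(rng, n)
    return DurationSample(
        durations=total,
        mean=float(total.mean()),
        sd=float(total.std(ddof=1)) if n > 1 else math.nan,
    )
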