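"""Measurement pipeline for combed-fiber replication tracks.

Classifies the labeled-segment patterns on each fiber into replication
structures, estimates per-fork velocities, scores replicon left/right
asymmetry, measures interorigin distances, and compares scenarios with the
Mann-Whitney U test.

Pattern grammar (I = first-pulse IdU, C = second-pulse CldU, U = unlabeled):

* ``origin replicon`` — an initiation event: either an unlabeled gap flanked
  by IdU on both sides (origin fired before the pulses; the gap midpoint is
  the initiation center) or an IdU block flanked by CldU on both sides
  (origin fired during pulse 1; the IdU midpoint is the center).
* ``ongoing fork`` — an IdU segment with CldU on exactly one side whose CldU
  does not abut further IdU (that would be a termination junction).  The two
  arms of a gap-centred replicon are themselves ongoing forks.
* ``termination`` — a CldU block flanked by IdU on both sides (converging
  forks met during pulse 2), or an IdU block between two initiation gaps
  (they met during pulse 1).
* ``first_pulse_only`` / ``second_pulse_only`` — isolated IdU (fork arrested
  before the second pulse) / isolated CldU (origin fired during pulse 2).

Structures touching fiber ends are flagged censored and take part in no
statistic.  Fork velocity defaults to total IdU+CldU length over total pulse
time; asymmetry is scored on the second-pulse (CldU) flank lengths.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .combing import Fiber, UnitConversion
from .distributions import SpecError
from .repsim import CLDU, IDU, UNLABELED

__all__ = [
    "AnalysisParams",
    "ReplicationStructure",
    "VelocityEstimate",
    "ComparisonResult",
    "CombingReport",
    "classify_structures",
    "estimate_fork_velocity",
    "asymmetry_score",
    "classify_asymmetric",
    "interorigin_distances",
    "interorigin_pairs",
    "iod_corrected_mean",
    "mann_whitney",
    "analyze_scenario",
    "compare_scenarios",
]

_ASYM_RULES = {"relative_max", "relative_min", "relative_mean"}


@dataclass(frozen=True)
class AnalysisParams:
    conv: UnitConversion = UnitConversion()
    pulse1_duration: float = 20.0  # minutes
    pulse2_duration: float = 20.0
    asymmetry_threshold: float = 0.3
    asymmetry_rule: str = "relative_max"
    velocity_mode: str = "total"  # "total" | "second_pulse_only"
    edge_margin: float = 1.0  # kb; structures this close to a fiber end are censored
    min_forks: int = 500
    n_replicates: int = 3  # pseudo-replicate grouping for mean +/- sd

    def __post_init__(self) -> None:
        if not 0 < self.asymmetry_threshold < 1:
            raise SpecError("asymmetry_threshold must be in (0, 1)")
        if self.pulse1_duration <= 0 or self.pulse2_duration <= 0:
            raise SpecError("pulse durations must be > 0")
        if self.velocity_mode not in {"total", "second_pulse_only"}:
            raise SpecError("velocity_mode must be 'total' or 'second_pulse_only'")
        if self.asymmetry_rule not in _ASYM_RULES:
            raise SpecError(f"asymmetry_rule must be one of {sorted(_ASYM_RULES)}")


@dataclass
class ReplicationStructure:
    kind: str  # ongoing_fork | origin_replicon | termination | first_pulse_only | second_pulse_only
    fiber_id: str
    idu_length: float = 0.0
    cldu_length: float = 0.0
    left_cldu: float | None = None
    right_cldu: float | None = None
    center_position: float | None = None  # fiber coordinates, kb
    censored: bool = False
    # extent of the segments an origin call depends on (its I/gap/I or C-I-C
    # core); a fragmentation cut inside this window censors the call
    core_start: float | None = None
    core_end: float | None = None

    @property
    def asymmetry_eligible(self) -> bool:
        return (
            self.kind == "origin_replicon"
            and not self.censored
            and self.left_cldu is not None
            and self.right_cldu is not None
            and self.left_cldu > 0
            and self.right_cldu > 0
        )


@dataclass
class VelocityEstimate:
    velocities: np.ndarray  # kb/min, one per eligible fork
    mean: float
    sd: float
    n: int

    @classmethod
    def from_velocities(cls, v: np.ndarray) -> "VelocityEstimate":
        v = np.asarray(v, dtype=float)
        if v.size and (v <= 0).any():
            raise AssertionError("fork velocities must be > 0")
        return cls(
            velocities=v,
            mean=float(v.mean()) if v.size else math.nan,
            sd=float(v.std(ddof=1)) if v.size > 1 else math.nan,
            n=int(v.size),
        )


@dataclass(frozen=True)
class ComparisonResult:
    U: float
    p: float
    n1: int
    n2: int
    direction: str  # "a_greater" | "b_greater" | "none"
    method: str  # "exact" | "normal"


# ----------------------------------------------------------------------
# Structure classification
# ----------------------------------------------------------------------
def classify_structures(fiber: Fiber, params: AnalysisParams) -> list[ReplicationStructure]:
    """Parse a fiber's labeled-segment pattern into replication structures."""
    fiber.check_invariants()
    segs = fiber.segments
    n = len(segs)

    def lab(i: int) -> str | None:
        return segs[i].label if 0 <= i < n else None

    margin = params.edge_margin

    def terminal(i: int) -> bool:
        # near a fiber end within optical resolution counts as touching it
        return segs[i].start < margin or segs[i].end > fiber.length - margin

    def touches_end(*idx: int) -> bool:
        return any(terminal(i) for i in idx if 0 <= i < n)

    def clean_flank(c_idx: int, far_idx: int) -> float | None:
        """CldU flank length, or None if absent or merged with a neighbour."""
        if lab(c_idx) != CLDU:
            return None
        if lab(far_idx) == IDU:  # shared termination CldU
            return None
        if terminal(c_idx):
            return None
        return segs[c_idx].length

    structures: list[ReplicationStructure] = []
    consumed_forks: set[tuple[int, int]] = set()

    origin_gap = [False] * n
    for j in range(n):
        if lab(j) == UNLABELED and lab(j - 1) == IDU and lab(j + 1) == IDU:
            origin_gap[j] = True

    # --- origin replicons ------------------------------------------------
    for j in range(n):
        if origin_gap[j]:
            censored = touches_end(j - 1, j, j + 1)
            structures.append(
                ReplicationStructure(
                    kind="origin_replicon",
                    fiber_id=fiber.fiber_id,
                    idu_length=segs[j - 1].length + segs[j + 1].length,
                    left_cldu=clean_flank(j - 2, j - 3),
                    right_cldu=clean_flank(j + 2, j + 3),
                    cldu_length=(segs[j - 2].length if lab(j - 2) == CLDU else 0.0)
                    + (segs[j + 2].length if lab(j + 2) == CLDU else 0.0),
                    center_position=0.5 * (segs[j].start + segs[j].end),
                    censored=censored,
                    core_start=segs[j - 1].start,
                    core_end=segs[j + 1].end,
                )
            )
        elif lab(j) == IDU and lab(j - 1) == CLDU and lab(j + 1) == CLDU:
            # origin fired during pulse 1: merged IdU center
            censored = touches_end(j - 1, j, j + 1)
            structures.append(
                ReplicationStructure(
                    kind="origin_replicon",
                    fiber_id=fiber.fiber_id,
                    idu_length=segs[j].length,
                    left_cldu=clean_flank(j - 1, j - 2),
                    right_cldu=clean_flank(j + 1, j + 2),
                    cldu_length=segs[j - 1].length + segs[j + 1].length,
                    center_position=0.5 * (segs[j].start + segs[j].end),
                    censored=censored,
                    core_start=segs[j - 1].start,
                    core_end=segs[j + 1].end,
                )
            )
            consumed_forks.add((j, j - 1))
            consumed_forks.add((j, j + 1))

    # --- terminations ----------------------------------------------------
    for j in range(n):
        if lab(j) == CLDU and lab(j - 1) == IDU and lab(j + 1) == IDU:
            structures.append(
                ReplicationStructure(
                    kind="termination",
                    fiber_id=fiber.fiber_id,
                    cldu_length=segs[j].length,
                    censored=touches_end(j - 1, j, j + 1),
                )
            )
            consumed_forks.add((j - 1, j))
            consumed_forks.add((j + 1, j))
    for j in range(n):
        # forks that met during pulse 1: an IdU block between two initiation gaps
        if lab(j) == IDU and j - 1 >= 0 and j + 1 < n and origin_gap[j - 1] and origin_gap[j + 1]:
            structures.append(
                ReplicationStructure(
                    kind="termination",
                    fiber_id=fiber.fiber_id,
                    idu_length=segs[j].length,
                    censored=touches_end(j),
                )
            )

    # --- ongoing forks ---------------------------------------------------
    for j in range(n):
        if lab(j) != IDU:
            continue
        if lab(j - 1) == CLDU and lab(j + 1) == CLDU:
            continue  # pulse-1-fired origin center (shared IdU)
        for c_idx in (j - 1, j + 1):
            if lab(c_idx) != CLDU or (j, c_idx) in consumed_forks:
                continue
            far = c_idx + (c_idx - j)
            if lab(far) == IDU:
                continue  # the CldU is a merged termination junction
            structures.append(
                ReplicationStructure(
                    kind="ongoing_fork",
                    fiber_id=fiber.fiber_id,
                    idu_length=segs[j].length,
                    cldu_length=segs[c_idx].length,
                    censored=touches_end(j, c_idx),
                )
            )
            consumed_forks.add((j, c_idx))

    # --- isolated tracks -------------------------------------------------
    for j in range(n):
        if lab(j) == IDU:
            has_c = CLDU in (lab(j - 1), lab(j + 1))
            near_gap = (j - 1 >= 0 and origin_gap[j - 1]) or (j + 1 < n and origin_gap[j + 1])
            if not has_c and not near_gap:
                structures.append(
                    ReplicationStructure(
                        kind="first_pulse_only",
                        fiber_id=fiber.fiber_id,
                        idu_length=segs[j].length,
                        censored=touches_end(j),
                    )
                )
        elif lab(j) == CLDU:
            if lab(j - 1) != IDU and lab(j + 1) != IDU:
                structures.append(
                    ReplicationStructure(
                        kind="second_pulse_only",
                        fiber_id=fiber.fiber_id,
                        cldu_length=segs[j].length,
                        censored=touches_end(j),
                    )
                )
    return structures


# ----------------------------------------------------------------------
# Per-structure statistics
# ----------------------------------------------------------------------
def estimate_fork_velocity(
    struct: ReplicationStructure, params: AnalysisParams
) -> float | None:
    """Velocity of one eligible ongoing fork, kb/min; ``None`` if ineligible.

    ``total`` mode divides the combined IdU+CldU track length by the total
    pulse time; ``second_pulse_only`` divides the CldU length by the second
    pulse time."""
    if struct.kind != "ongoing_fork" or struct.censored:
        return None
    if params.velocity_mode == "total":
        if struct.idu_length <= 0 or struct.cldu_length <= 0:
            return None
        return (struct.idu_length + struct.cldu_length) / (
            params.pulse1_duration + params.pulse2_duration
        )
    if struct.cldu_length <= 0:
        return None
    return struct.cldu_length / params.pulse2_duration


def asymmetry_score(left_cldu: float, right_cldu: float, rule: str = "relative_max") -> float:
    """Left/right discordance of a replicon's second-pulse flanks.

    Default: |L - R| / max(L, R), bounded in [0, 1).  Alternative readings of
    the +/-0.3 rule: ``relative_min`` (equivalent to requiring L/R within a
    ratio band) and ``relative_mean``."""
    if left_cldu <= 0 or right_cldu <= 0:
        raise SpecError("asymmetry requires both flanks > 0")
    d = abs(left_cldu - right_cldu)
    if rule == "relative_max":
        return d / max(left_cldu, right_cldu)
    if rule == "relative_min":
        return d / min(left_cldu, right_cldu)
    if rule == "relative_mean":
        return d / (0.5 * (left_cldu + right_cldu))
    raise SpecError(f"unknown asymmetry rule {rule!r}")


def classify_asymmetric(score: float, params: AnalysisParams) -> bool:
    """A replicon is asymmetrical when its score exceeds the threshold."""
    return score > params.asymmetry_threshold


def interorigin_pairs(
    fibers: list[Fiber], params: AnalysisParams,
    structures: list[list[ReplicationStructure]] | None = None,
) -> list[tuple[float, float, float]]:
    """Consecutive-origin pairs per fiber: (distance, span, fiber_length), kb.

    ``span`` is the window a fragmentation cut must avoid for the pair to be
    observable (from the left origin's core start to the right origin's core
    end); it feeds the length-bias correction of the mean IOD."""
    if structures is None:
        structures = [classify_structures(f, params) for f in fibers]
    pairs: list[tuple[float, float, float]] = []
    for fiber, fiber_structs in zip(fibers, structures):
        origins = sorted(
            (
                s
                for s in fiber_structs
                if s.kind == "origin_replicon" and not s.censored and s.center_position is not None
            ),
            key=lambda s: s.center_position,
        )
        for a, b in itertools.pairwise(origins):
            dist = b.center_position - a.center_position
            span = (b.core_end or b.center_position) - (a.core_start or a.center_position)
            pairs.append((dist, span, fiber.length))
    return pairs


def interorigin_distances(
    fibers: list[Fiber], params: AnalysisParams,
    structures: list[list[ReplicationStructure]] | None = None,
) -> np.ndarray:
    """Center-to-center distances between consecutive eligible origins, kb.

    Distances are measured within each fiber and pooled across fibers."""
    pairs = interorigin_pairs(fibers, params, structures)
    if not pairs:
        warnings.warn("fewer than 2 eligible origins on every fiber", stacklevel=2)
    return np.asarray([p[0] for p in pairs], dtype=float)


def iod_corrected_mean(
    pairs: list[tuple[float, float, float]], min_window_frac: float = 0.25
) -> float:
    """Length-bias-corrected mean interorigin distance.

    A pair whose required span is s can only be observed on a fiber longer
    than s, with inclusion probability proportional to (fiber length - s);
    inverse-probability (Horvitz-Thompson) weighting removes the resulting
    under-representation of long distances.  Weights are truncated at
    1/(``min_window_frac`` x median fiber length) to keep near-span-filling
    pairs from dominating the estimate."""
    if not pairs:
        return math.nan
    lengths = np.array([p[2] for p in pairs])
    floor = min_window_frac * float(np.median(lengths))
    w = np.array([1.0 / max(L - s, floor) for _, s, L in pairs])
    d = np.array([p[0] for p in pairs])
    return float((w * d).sum() / w.sum())


# ----------------------------------------------------------------------
# Mann-Whitney U
# ----------------------------------------------------------------------
def mann_whitney(sample_a, sample_b, exact_limit: int = 12) -> ComparisonResult:
    """Two-sided Mann-Whitney U test with tie handling.

    The null distribution is enumerated exactly (all label assignments of the
    pooled values, midranks for ties) when n1 + n2 <= ``exact_limit``;
    otherwise the tie-corrected normal approximation with continuity
    correction is used.  U is reported for ``sample_a``."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SpecError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    m = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        count = 0
        total = 0
        obs_dev = abs(u1 - m)
        idx_all = range(n1 + n2)
        for combo in itertools.combinations(idx_all, n1):
            u = float(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0)
            if abs(u - m) >= obs_dev - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        N = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
        sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            dev = abs(u1 - m)
            z = max(dev - 0.5, 0.0) / math.sqrt(sigma2)
            p = min(2.0 * stats.norm.sf(z), 1.0)
        method = "normal"

    if u1 > m:
        direction = "a_greater"
    elif u1 < m:
        direction = "b_greater"
    else:
        direction = "none"
    return ComparisonResult(U=u1, p=max(p, np.finfo(float).tiny), n1=n1, n2=n2,
                            direction=direction, method=method)


# ----------------------------------------------------------------------
# Scenario-level report
# ----------------------------------------------------------------------
@dataclass
class CombingReport:
    scenario_name: str
    velocity: VelocityEstimate
    asymmetry_scores: np.ndarray
    asymmetric_fraction: float
    asymmetric_fraction_by_replicate: list[float]
    asymmetric_fraction_mean: float
    asymmetric_fraction_sd: float
    interorigin_distances_kb: np.ndarray
    iod_mean: float  # length-bias-corrected (headline measurement)
    iod_mean_raw: float  # plain pooled mean
    n_replicons: int
    counts: dict[str, int] = field(default_factory=dict)
    insufficient_data: bool = False

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_name,
            "velocity_mean_kb_per_min": self.velocity.mean,
            "velocity_sd": self.velocity.sd,
            "n_forks": self.velocity.n,
            "asymmetric_fraction": self.asymmetric_fraction,
            "asymmetric_fraction_by_replicate": list(self.asymmetric_fraction_by_replicate),
            "asymmetric_fraction_mean": self.asymmetric_fraction_mean,
            "asymmetric_fraction_sd": self.asymmetric_fraction_sd,
            "n_replicons": self.n_replicons,
            "iod_mean_kb": self.iod_mean,
            "iod_mean_raw_kb": self.iod_mean_raw,
            "n_interorigin_distances": int(self.interorigin_distances_kb.size),
            "counts": dict(self.counts),
            "insufficient_data": self.insufficient_data,
            "velocities_kb_per_min": [float(v) for v in self.velocity.velocities],
            "interorigin_distances_kb": [float(d) for d in self.interorigin_distances_kb],
        }


def analyze_scenario(
    fibers: list[Fiber], params: AnalysisParams, scenario_name: str = ""
) -> CombingReport:
    """Run the full measurement pipeline over a set of fibers."""
    per_fiber = [classify_structures(f, params) for f in fibers]

    velocities = []
    counts: dict[str, int] = {}
    for structs in per_fiber:
        for s in structs:
            counts[s.kind] = counts.get(s.kind, 0) + 1
            v = estimate_fork_velocity(s, params)
            if v is not None:
                velocities.append(v)
    vel = VelocityEstimate.from_velocities(np.asarray(velocities))

    # asymmetry on eligible replicons; fibers grouped round-robin into
    # pseudo-replicates to mimic independent experiments
    scores_all: list[float] = []
    by_rep_scores: list[list[float]] = [[] for _ in range(params.n_replicates)]
    for i, structs in enumerate(per_fiber):
        rep = i % params.n_replicates
        for s in structs:
            if s.asymmetry_eligible:
                sc = asymmetry_score(s.left_cldu, s.right_cldu, params.asymmetry_rule)
                scores_all.append(sc)
                by_rep_scores[rep].append(sc)
    scores = np.asarray(scores_all)
    frac = float((scores > params.asymmetry_threshold).mean()) if scores.size else math.nan
    rep_fracs = [
        float((np.asarray(ss) > params.asymmetry_threshold).mean()) for ss in by_rep_scores if ss
    ]
    pairs = interorigin_pairs(fibers, params, structures=per_fiber) if fibers else []
    if fibers and not pairs:
        warnings.warn("fewer than 2 eligible origins on every fiber", stacklevel=2)
    iods = np.asarray([p[0] for p in pairs], dtype=float)

    return CombingReport(
        scenario_name=scenario_name,
        velocity=vel,
        asymmetry_scores=scores,
        asymmetric_fraction=frac,
        asymmetric_fraction_by_replicate=rep_fracs,
        asymmetric_fraction_mean=float(np.mean(rep_fracs)) if rep_fracs else math.nan,
        asymmetric_fraction_sd=float(np.std(rep_fracs, ddof=1)) if len(rep_fracs) > 1 else math.nan,
        interorigin_distances_kb=iods,
        iod_mean=iod_corrected_mean(pairs),
        iod_mean_raw=float(iods.mean()) if iods.size else math.nan,
        n_replicons=len(scores_all),
        counts=counts,
        insufficient_data=vel.n < params.min_forks,
    )


def compare_scenarios(report_a: CombingReport, report_b: CombingReport) -> dict[str, ComparisonResult]:
    """Mann-Whitney comparisons of the velocity and IOD samples of two runs."""
    out: dict[str, ComparisonResult] = {}
    if report_a.velocity.n and report_b.velocity.n:
        out["velocity"] = mann_whitney(report_a.velocity.velocities, report_b.velocity.velocities)
    if report_a.interorigin_distances_kb.size and report_b.interorigin_distances_kb.size:
        out["interorigin_distance"] = mann_whitney(
            report_a.interorigin_distances_kb, report_b.interorigin_distances_kb
        )
    return out
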