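"""Small declarative distribution specifications used by scenario configs.

Every stochastic ingredient of a scenario (origin spacing, firing times,
per-replicon velocities, fiber lengths, phase durations) is described by a
:class:`DistributionSpec` so that configs stay plain YAML and sampling is
centralised and reproducible.  Supported families:

``fixed``        point mass at ``mean``
``exponential``  mean ``mean``
``gamma``        mean ``mean`` and either ``shape`` (k) or ``cv``
``lognormal``    mean ``mean`` and ``sigma_log`` (sd of log)
``normal``       ``mean`` and ``sd`` or ``cv``
``uniform``      ``low`` .. ``high``
``mixture``      weighted list of component specs
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["DistributionSpec", "SpecError"]


class SpecError(ValueError):
    """Raised when a distribution or scenario specification is invalid."""


_FAMILIES = {"fixed", "exponential", "gamma", "lognormal", "normal", "uniform", "mixture"}


@dataclass(frozen=True)
class DistributionSpec:
    family: str
    mean: float | None = None
    shape: float | None = None
    cv: float | None = None
    sigma_log: float | None = None
    sd: float | None = None
    low: float | None = None
    high: float | None = None
    components: tuple["DistributionSpec", ...] = ()
    weights: tuple[float, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise SpecError(f"unknown distribution family {self.family!r}")
        if self.family == "mixture":
            if not self.components:
                raise SpecError("mixture requires components")
            if len(self.weights) != len(self.components):
                raise SpecError("mixture weights must match components")
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or w.sum() <= 0:
                raise SpecError("mixture weights must be non-negative and sum > 0")
        elif self.family == "uniform":
            if self.low is None or self.high is None or not self.high > self.low:
                raise SpecError("uniform requires low < high")
        else:
            if self.mean is None:
                raise SpecError(f"{self.family} requires a mean")
            if self.family in {"exponential", "gamma", "lognormal"} and self.mean <= 0:
                raise SpecError(f"{self.family} mean must be > 0")
            if self.family == "gamma" and self.shape is None and self.cv is None:
                raise SpecError("gamma requires shape or cv")
            if self.family == "lognormal":
                if self.sigma_log is None and self.cv is None:
                    raise SpecError("lognormal requires sigma_log or cv")
                if self.sigma_log is not None and self.sigma_log < 0:
                    raise SpecError("lognormal sigma_log must be >= 0")
            if self.family == "normal" and self.sd is None and self.cv is None:
                raise SpecError("normal requires sd or cv")

    # ------------------------------------------------------------------
    @property
    def expectation(self) -> float:
        """Analytic mean of the distribution."""
        if self.family == "uniform":
            return 0.5 * (self.low + self.high)
        if self.family == "mixture":
            w = np.asarray(self.weights, dtype=float)
            w = w / w.sum()
            return float(sum(wi * c.expectation for wi, c in zip(w, self.components)))
        return float(self.mean)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` iid values."""
        if size < 0:
            raise SpecError("size must be >= 0")
        if self.family == "fixed":
            return np.full(size, float(self.mean))
        if self.family == "exponential":
            return rng.exponential(self.mean, size)
        if self.family == "gamma":
            k = self.shape if self.shape is not None else 1.0 / (self.cv**2)
            return rng.gamma(k, self.mean / k, size)
        if self.family == "lognormal":
            s = (
                self.sigma_log
                if self.sigma_log is not None
                else math.sqrt(math.log1p(self.cv**2))
            )
            if s == 0:
                return np.full(size, float(self.mean))
            mu = np.log(self.mean) - 0.5 * s**2
            return rng.lognormal(mu, s, size)
        if self.family == "normal":
            sd = self.sd if self.sd is not None else abs(self.cv * self.mean)
            return rng.normal(self.mean, sd, size)
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size)
        # mixture
        w = np.asarray(self.weights, dtype=float)
        w = w / w.sum()
        idx = rng.choice(len(self.components), size=size, p=w)
        out = np.empty(size)
        for i, comp in enumerate(self.components):
            mask = idx == i
            out[mask] = comp.sample(rng, int(mask.sum()))
        return out

    def sample_one(self, rng: np.random.Generator) -> float:
        return float(self.sample(rng, 1)[0])

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DistributionSpec":
        if not isinstance(d, dict) or "family" not in d:
            raise SpecError(f"distribution spec must be a mapping with a 'family': got {d!r}")
        d = dict(d)
        fam = d.pop("family")
        comps = tuple(cls.from_dict(c) for c in d.pop("components", []))
        weights = tuple(float(w) for w in d.pop("weights", []))
        known = {"mean", "shape", "cv", "sigma_log", "sd", "low", "high"}
        kwargs = {k: float(v) for k, v in d.items() if k in known and v is not None}
        unknown = set(d) - known
        if unknown:
            raise SpecError(f"unknown distribution keys: {sorted(unknown)}")
        return cls(family=fam, components=comps, weights=weights, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"family": self.family}
        for k in ("mean", "shape", "cv", "sigma_log", "sd", "low", "high"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        if self.components:
            out["components"] = [c.to_dict() for c in self.components]
            out["weights"] = list(self.weights)
        return out
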