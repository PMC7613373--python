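"""Random sampling of the simulation parameter space.

The default parameter space spans typical agricultural canopies: uniform
marginals for most leaf and canopy variables, truncated Gaussians for leaf
protein content and leaf area index (the two drivers of canopy nitrogen
content), and fixed sun/view geometry (sun zenith 30 deg, nadir view).
Truncated Gaussians are drawn by rejection inside their bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .prospect import LeafParams
from .sail import CanopyParams, ViewGeometry

__all__ = [
    "VariableSpec",
    "ParameterSpace",
    "DEFAULT_PARAMETER_SPACE",
    "sample_parameters",
]


@dataclass(frozen=True)
class VariableSpec:
    """Marginal distribution of one simulation variable."""

    min: float
    max: float
    distribution: str = "uniform"  # "uniform" | "gaussian" (truncated)
    mean: float | None = None
    sd: float | None = None

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.distribution == "uniform":
            return rng.uniform(self.min, self.max, n)
        if self.distribution == "gaussian":
            out = np.empty(n)
            have = 0
            while have < n:
                cand = rng.normal(self.mean, self.sd, 2 * (n - have) + 16)
                cand = cand[(cand >= self.min) & (cand <= self.max)]
                take = min(cand.size, n - have)
                out[have : have + take] = cand[:take]
                have += take
            return out
        raise ValueError(f"unknown distribution {self.distribution!r}")

    def to_dict(self) -> dict:
        d = {"min": self.min, "max": self.max, "distribution": self.distribution}
        if self.distribution == "gaussian":
            d.update(mean=self.mean, sd=self.sd)
        return d


def _default_variables() -> dict[str, VariableSpec]:
    return {
        "N_struct": VariableSpec(1.0, 2.5),
        "C_ab": VariableSpec(0.0, 80.0),
        "C_w": VariableSpec(0.001, 0.02),
        "C_xc": VariableSpec(0.0, 15.0),
        "C_anth": VariableSpec(0.0, 2.0),
        "C_p": VariableSpec(0.001, 0.0025, "gaussian", mean=0.0015, sd=0.0005),
        "CBC": VariableSpec(0.001, 0.01),
        "LAI": VariableSpec(0.1, 7.0, "gaussian", mean=3.0, sd=2.0),
        "alpha_soil": VariableSpec(0.0, 1.0),
        "ALA": VariableSpec(30.0, 70.0),
        "HotS": VariableSpec(0.01, 0.5),
    }


@dataclass(frozen=True)
class ParameterSpace:
    """Full sampling configuration: marginals plus fixed geometry."""

    variables: dict[str, VariableSpec] = field(default_factory=_default_variables)
    SZA: float = 30.0
    OZA: float = 0.0
    rel_azimuth: float = 0.0

    def to_dict(self) -> dict:
        return {
            "variables": {k: v.to_dict() for k, v in self.variables.items()},
            "SZA": self.SZA,
            "OZA": self.OZA,
            "rel_azimuth": self.rel_azimuth,
        }

    @staticmethod
    def from_dict(d: dict) -> "ParameterSpace":
        variables = {k: VariableSpec(**v) for k, v in d.get("variables", {}).items()}
        if not variables:
            variables = _default_variables()
        return ParameterSpace(
            variables,
            SZA=d.get("SZA", 30.0),
            OZA=d.get("OZA", 0.0),
            rel_azimuth=d.get("rel_azimuth", 0.0),
        )


DEFAULT_PARAMETER_SPACE = ParameterSpace()

_LEAF_FIELDS = ("N_struct", "C_ab", "C_xc", "C_anth", "C_w", "C_p", "CBC")
_CANOPY_FIELDS = ("LAI", "ALA", "HotS", "alpha_soil")


def sample_parameters(
    n: int,
    seed: int | np.random.Generator | None = None,
    space: ParameterSpace = DEFAULT_PARAMETER_SPACE,
) -> list[tuple[LeafParams, CanopyParams, ViewGeometry]]:
    """Draw ``n`` independent canopy states; reproducible per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draws = {name: spec.draw(n, rng) for name, spec in space.variables.items()}
    geom = ViewGeometry(space.SZA, space.OZA, space.rel_azimuth)
    out = []
    for i in range(n):
        leaf = LeafParams(**{f: float(draws[f][i]) for f in _LEAF_FIELDS})
        canopy = CanopyParams(**{f: float(draws[f][i]) for f in _CANOPY_FIELDS})
        out.append((leaf, canopy, geom))
    return out


def iter_param_dicts(
    samples: list[tuple[LeafParams, CanopyParams, ViewGeometry]],
) -> Iterator[dict]:
    for leaf, canopy, geom in samples:
        d = {f: getattr(leaf, f) for f in _LEAF_FIELDS}
        d.update({f: getattr(canopy, f) for f in _CANOPY_FIELDS})
        d.update(SZA=geom.SZA, OZA=geom.OZA)
        yield d
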