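"""Distribution descriptors used by the synthetic-data generators.

A :class:`DistributionLaw` is a small, serialisable description of a 1-D
probability law (family name plus parameters).  It exists so that synthetic
field configurations can be written to YAML, compared, and rescaled (for
treatment-effect scenarios) without carrying frozen RNG state around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

_FAMILIES = {
    "constant",
    "uniform",
    "normal",
    "lognormal",
    "poisson",
    "shifted_poisson",
}


@dataclass(frozen=True)
class DistributionLaw:
    """A named 1-D distribution with parameters.

    Supported families and their parameters:

    ``constant``
        ``value``
    ``uniform``
        ``low``, ``high`` (continuous, half-open ``[low, high)``)
    ``normal``
        ``mean``, ``sd``
    ``lognormal``
        ``mu``, ``sigma`` (parameters of the underlying normal on log scale)
    ``poisson``
        ``lam``
    ``shifted_poisson``
        ``shift``, ``lam`` — ``shift + Poisson(lam)``; with integer shift ≥ 1
        this guarantees counts of at least ``shift``.
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))
        p = self.params
        need = {
            "constant": {"value"},
            "uniform": {"low", "high"},
            "normal": {"mean", "sd"},
            "lognormal": {"mu", "sigma"},
            "poisson": {"lam"},
            "shifted_poisson": {"shift", "lam"},
        }[self.family]
        if set(p) != need:
            raise ValueError(
                f"{self.family} law needs parameters {sorted(need)}, got {sorted(p)}"
            )
        if self.family == "uniform" and not p["low"] < p["high"]:
            raise ValueError("uniform law needs low < high")
        if self.family == "normal" and p["sd"] < 0:
            raise ValueError("normal sd must be non-negative")
        if self.family == "lognormal" and p["sigma"] < 0:
            raise ValueError("lognormal sigma must be non-negative")
        if self.family in ("poisson", "shifted_poisson") and p["lam"] < 0:
            raise ValueError("poisson rate must be non-negative")

    # -- moments -----------------------------------------------------------

    @property
    def mean(self) -> float:
        p = self.params
        if self.family == "constant":
            return float(p["value"])
        if self.family == "uniform":
            return (p["low"] + p["high"]) / 2.0
        if self.family == "normal":
            return float(p["mean"])
        if self.family == "lognormal":
            return math.exp(p["mu"] + p["sigma"] ** 2 / 2.0)
        if self.family == "poisson":
            return float(p["lam"])
        return p["shift"] + p["lam"]

    @property
    def support_min(self) -> float:
        p = self.params
        if self.family == "constant":
            return float(p["value"])
        if self.family == "uniform":
            return float(p["low"])
        if self.family == "normal":
            return -math.inf
        if self.family == "lognormal":
            return 0.0
        if self.family == "poisson":
            return 0.0
        return float(p["shift"])

    @property
    def is_integer(self) -> bool:
        return self.family in ("poisson", "shifted_poisson") or (
            self.family == "constant" and float(self.params["value"]).is_integer()
        )

    # -- sampling ----------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "constant":
            out = np.full(size, p["value"], dtype=float)
        elif self.family == "uniform":
            out = rng.uniform(p["low"], p["high"], size)
        elif self.family == "normal":
            out = rng.normal(p["mean"], p["sd"], size)
        elif self.family == "lognormal":
            out = rng.lognormal(p["mu"], p["sigma"], size)
        elif self.family == "poisson":
            out = rng.poisson(p["lam"], size).astype(float)
        else:
            out = p["shift"] + rng.poisson(p["lam"], size).astype(float)
        return out

    def sample_counts(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Sample and round to non-negative integer counts."""
        return np.maximum(np.rint(self.sample(rng, size)), 0).astype(int)

    # -- transforms --------------------------------------------------------

    def with_mean(self, new_mean: float) -> "DistributionLaw":
        """Return the same family rescaled/shifted to a new mean.

        Used to apply a treatment-effect multiplier to a density law.
        """
        if new_mean <= 0:
            raise ValueError("target mean must be positive")
        p = dict(self.params)
        if self.family == "constant":
            p["value"] = new_mean
        elif self.family == "uniform":
            s = new_mean / self.mean
            p["low"] *= s
            p["high"] *= s
        elif self.family == "normal":
            p["mean"] = new_mean
        elif self.family == "lognormal":
            p["mu"] += math.log(new_mean / self.mean)
        elif self.family == "poisson":
            p["lam"] = new_mean
        else:  # shifted_poisson: keep the shift, move the Poisson part
            lam = new_mean - p["shift"]
            if lam < 0:
                raise ValueError(
                    f"cannot reach mean {new_mean} with shift {p['shift']}"
                )
            p["lam"] = lam
        return DistributionLaw(self.family, p)

    def scaled_mean(self, multiplier: float) -> "DistributionLaw":
        if multiplier <= 0:
            raise ValueError("multiplier must be positive")
        return self.with_mean(self.mean * multiplier)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionLaw":
        return cls(d["family"], d["params"])


def constant(value: float) -> DistributionLaw:
    return DistributionLaw("constant", {"value": value})


def uniform(low: float, high: float) -> DistributionLaw:
    return DistributionLaw("uniform", {"low": low, "high": high})


def normal(mean: float, sd: float) -> DistributionLaw:
    return DistributionLaw("normal", {"mean": mean, "sd": sd})


def lognormal(mu: float, sigma: float) -> DistributionLaw:
    return DistributionLaw("lognormal", {"mu": mu, "sigma": sigma})


def poisson(lam: float) -> DistributionLaw:
    return DistributionLaw("poisson", {"lam": lam})


def shifted_poisson(shift: int, lam: float) -> DistributionLaw:
    return DistributionLaw("shifted_poisson", {"shift": shift, "lam": lam})
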