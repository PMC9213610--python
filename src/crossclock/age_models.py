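"""Age transformations shared by the clocks.

Two transforms put chronological ages of species with very different
lifespans on comparable scales:

* **relative age** — age divided by the species' maximum lifespan, the
  standard lifespan normalization for dual-species clocks.  An opossum
  halfway through a 4.2-year lifespan and a human halfway through a
  122.5-year one both map to 0.5.
* **log-linear age** — logarithmic before the species' age at sexual
  maturity ``m`` and linear after it, continuous at the knot:
  ``y = log((a + k) / (m + k))`` for ``a < m``, else ``(a - m) / (m + k)``.
  The log segment expands the fast developmental epoch, the linear segment
  keeps adult ages on the calendar scale.  ``k`` (years) guards against
  ``log(0)`` at birth; default 1.0.

Both transforms are strictly increasing and have closed-form inverses, which
prediction requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

TRANSFORM_KINDS = ("identity", "relative", "loglinear")

#: default log-linear offset k, in years
DEFAULT_LOGLINEAR_OFFSET = 1.0


def relative_age(age_years, max_lifespan_years):
    """Relative age = age / maximum lifespan.

    Values above 1 are possible (an animal outliving the recorded species
    maximum) and are returned unclamped with a warning; [0, 1] is the
    designed range, not a hard bound.
    """
    age = np.asarray(age_years, dtype=float)
    lifespan = np.asarray(max_lifespan_years, dtype=float)
    if np.any(lifespan <= 0):
        raise ValueError("max_lifespan_years must be positive")
    if np.any(age < 0):
        raise ValueError("age_years must be non-negative")
    out = age / lifespan
    if np.any(out > 1):
        logger.warning("relative age above 1 for %d value(s)", int(np.sum(out > 1)))
    return out if out.ndim else float(out)


def _check_loglinear_params(m, k) -> None:
    if np.any(np.asarray(m, dtype=float) <= 0):
        raise ValueError("maturity m must be positive")
    if np.any(np.asarray(k, dtype=float) <= 0):
        raise ValueError("offset k must be positive")


def loglinear_forward(age_years, m, k=DEFAULT_LOGLINEAR_OFFSET):
    """Piecewise log-linear transform: log before maturity, linear after.

    ``y(m) = 0``; both pieces share slope ``1/(m+k)`` at the knot, so the
    transform is C1 and strictly increasing.
    """
    _check_loglinear_params(m, k)
    age = np.asarray(age_years, dtype=float)
    if np.any(age < 0):
        raise ValueError("age_years must be non-negative")
    m = np.asarray(m, dtype=float)
    k = np.asarray(k, dtype=float)
    young = np.log((age + k) / (m + k))
    adult = (age - m) / (m + k)
    out = np.where(age < m, young, adult)
    return out if out.ndim else float(out)


def loglinear_inverse(y, m, k=DEFAULT_LOGLINEAR_OFFSET):
    """Exact inverse of :func:`loglinear_forward`, floored at age 0."""
    _check_loglinear_params(m, k)
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    k = np.asarray(k, dtype=float)
    young = np.exp(y) * (m + k) - k
    adult = y * (m + k) + m
    out = np.maximum(np.where(y < 0, young, adult), 0.0)
    return out if out.ndim else float(out)


@dataclass
class AgeTransformSpec:
    """Specification of the clock's age transform with per-species parameters.

    ``kind`` is one of identity / relative / loglinear.  ``lifespans`` maps
    species → max_lifespan_years (relative); ``maturities`` maps species →
    maturity m in years (loglinear); ``offset_k`` is the shared log-linear
    offset in years.
    """

    kind: str
    lifespans: dict[str, float] = field(default_factory=dict)
    maturities: dict[str, float] = field(default_factory=dict)
    offset_k: float = DEFAULT_LOGLINEAR_OFFSET

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "relative" and any(v <= 0 for v in self.lifespans.values()):
            raise ValueError("lifespans must be positive")
        if self.kind == "loglinear":
            if any(v <= 0 for v in self.maturities.values()):
                raise ValueError("maturities must be positive")
            if self.offset_k <= 0:
                raise ValueError("offset_k must be positive")

    def _per_sample(self, species, mapping: dict[str, float]) -> np.ndarray:
        try:
            return np.asarray([mapping[s] for s in species], dtype=float)
        except KeyError as e:
            raise KeyError(f"no transform parameter for species {e.args[0]!r}") from None

    def forward(self, age_years, species) -> np.ndarray:
        """Transform per-sample ages using each sample's species parameters."""
        age = np.asarray(age_years, dtype=float)
        if self.kind == "identity":
            return age.copy()
        if self.kind == "relative":
            return np.asarray(relative_age(age, self._per_sample(species, self.lifespans)))
        return np.asarray(
            loglinear_forward(age, self._per_sample(species, self.maturities), self.offset_k)
        )

    def inverse(self, y, species) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.kind == "identity":
            return y.copy()
        if self.kind == "relative":
            return y * self._per_sample(species, self.lifespans)
        return np.asarray(
            loglinear_inverse(y, self._per_sample(species, self.maturities), self.offset_k)
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "lifespans": dict(self.lifespans),
            "maturities": dict(self.maturities),
            "offset_k": self.offset_k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgeTransformSpec":
        return cls(
            kind=d["kind"],
            lifespans={k: float(v) for k, v in d.get("lifespans", {}).items()},
            maturities={k: float(v) for k, v in d.get("maturities", {}).items()},
            offset_k=float(d.get("offset_k", DEFAULT_LOGLINEAR_OFFSET)),
        )

    @classmethod
    def from_sample_sheet(cls, kind: str, sheet) -> "AgeTransformSpec":
        """Build a spec from the species constants of a sample sheet."""
        c = sheet.species_constants
        return cls(
            kind=kind,
            lifespans=dict(zip(c["species"], c["max_lifespan_years"].astype(float))),
            maturities=dict(zip(c["species"], c["maturity_years"].astype(float))),
        )
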