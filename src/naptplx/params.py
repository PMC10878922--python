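"""Parameter container and family-validity rules.

The distribution has four positive parameters:

* ``theta`` — Lomax tail shape (dimensionless),
* ``beta`` — power shape applied to the data (dimensionless),
* ``lam`` — scale, in the units of ``x**beta``,
* ``alpha`` — transform shape of the alpha-power map ``G -> G * alpha**G / alpha``.

``alpha = 1`` returns the baseline Power Lomax exactly.  The transform yields
a proper distribution only for ``alpha >= exp(-1)``: for smaller ``alpha`` the
density factor ``1 + G*log(alpha)`` goes negative on part of the support and
the "cdf" overshoots 1 at ``G = -1/log(alpha)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ALPHA_MIN",
    "ParameterVector",
    "InvalidParameterError",
    "InvalidFamilyError",
    "FamilyValidityWarning",
    "MomentExistenceError",
    "DataError",
    "validate_params",
]

#: lower validity bound for the transform shape, exp(-1)
ALPHA_MIN = math.exp(-1.0)


class InvalidParameterError(ValueError):
    """A parameter violates positivity."""


class InvalidFamilyError(ValueError):
    """alpha is below exp(-1): the transform does not define a distribution."""


class FamilyValidityWarning(UserWarning):
    """Emitted in permissive mode when alpha < exp(-1)."""


class MomentExistenceError(ValueError):
    """A requested moment order r >= theta*beta does not exist."""


class DataError(ValueError):
    """Observations violate the support (must be strictly positive)."""


@dataclass(frozen=True)
class ParameterVector:
    """The four distribution parameters, all strictly positive.

    Fixed field order ``(theta, beta, lam, alpha)`` everywhere; use keyword
    access to avoid positional mistakes.
    """

    theta: float
    beta: float
    lam: float
    alpha: float = 1.0

    @property
    def is_baseline(self) -> bool:
        """True when alpha == 1, i.e. the baseline Power Lomax."""
        return self.alpha == 1.0

    @property
    def is_strictly_valid(self) -> bool:
        """True when the transform defines a proper cdf (alpha >= exp(-1))."""
        return (
            self.theta > 0
            and self.beta > 0
            and self.lam > 0
            and self.alpha >= ALPHA_MIN
        )

    def moment_order_bound(self) -> float:
        """Raw moments of order ``r`` exist iff ``r < theta*beta``."""
        return self.theta * self.beta

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.beta, self.lam, self.alpha], dtype=float)

    @classmethod
    def from_array(cls, a) -> "ParameterVector":
        theta, beta, lam, alpha = (float(v) for v in a)
        return cls(theta=theta, beta=beta, lam=lam, alpha=alpha)

    def replace(self, **kw) -> "ParameterVector":
        return replace(self, **kw)


def validate_params(p: ParameterVector, strict: bool = True) -> ParameterVector:
    """Validate positivity and family validity; return ``p`` unchanged.

    Parameters
    ----------
    p
        Candidate parameter vector.
    strict
        If True (default) raise :class:`InvalidFamilyError` when
        ``alpha < exp(-1)``.  If False, emit :class:`FamilyValidityWarning`
        instead (useful only to demonstrate the pathology of invalid
        configurations).
    """
    for name in ("theta", "beta", "lam", "alpha"):
        v = getattr(p, name)
        if not np.isfinite(v) or v <= 0:
            raise InvalidParameterError(
                f"parameter {name!r} must be a positive finite number, got {v!r}"
            )
    if p.alpha < ALPHA_MIN:
        msg = (
            f"alpha={p.alpha!r} violates the family validity bound "
            f"alpha >= exp(-1) ≈ {ALPHA_MIN:.6f}: the transformed cdf "
            "G*alpha**(G-1) exceeds 1 at G = -1/log(alpha) and the density "
            "factor 1 + G*log(alpha) turns negative"
        )
        if strict:
            raise InvalidFamilyError(msg)
        warnings.warn(msg, FamilyValidityWarning, stacklevel=2)
    return p
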