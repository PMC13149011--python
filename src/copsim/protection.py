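"""Protection functions and the ground-truth IRR curves they imply.

A scalar correlate of protection (COP) ``X`` in [0, 1] removes a fraction
``psi(X)`` of the per-day infection hazard.  Three closed-form shapes are
supported: ``linear`` (psi = X, the primary specification), ``squared``
(psi = X**2) and ``cubic`` (psi = X**3).  All satisfy psi(0) = 0,
psi(1) = 1 and are monotone non-decreasing on [0, 1].

Because the hazard at COP level ``X`` and risk multiplier ``R`` is
``gamma * (1 - psi(X)) * (I + A) * R``, the incidence rate ratio relative
to an unprotected low-risk individual is ``(1 - psi(X)) * R`` — the target
curve every estimator in this package tries to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PROTECTION_FORMS", "ProtectionSpec", "psi", "true_irr"]

PROTECTION_FORMS = ("linear", "squared", "cubic")

_EXPONENT = {"linear": 1, "squared": 2, "cubic": 3}


@dataclass(frozen=True)
class ProtectionSpec:
    """Which protection shape is active.

    Parameters
    ----------
    form : {"linear", "squared", "cubic"}
        psi(X) = X, X**2 or X**3 respectively.
    """

    form: str = "linear"

    def __post_init__(self) -> None:
        if self.form not in PROTECTION_FORMS:
            raise ValueError(
                f"form must be one of {PROTECTION_FORMS}, got {self.form!r}"
            )

    @property
    def exponent(self) -> int:
        return _EXPONENT[self.form]


def _validate_cop(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("COP level must lie in [0, 1]")
    return x


def psi(x, spec: ProtectionSpec | str = "linear"):
    """Protection fraction psi(X) at COP level(s) ``x``.

    Accepts scalars or arrays; values outside [0, 1] are rejected.
    """
    if isinstance(spec, str):
        spec = ProtectionSpec(spec)
    x = _validate_cop(x)
    out = x ** spec.exponent
    return out if out.ndim else float(out)


def true_irr(x, spec: ProtectionSpec | str = "linear", risk=1):
    """True incidence rate ratio (1 - psi(X)) * R.

    The reference category is a low-risk individual with X = 0, so the
    curve runs from ``risk`` at X = 0 down to 0 at X = 1.
    """
    if isinstance(spec, str):
        spec = ProtectionSpec(spec)
    x = _validate_cop(x)
    risk = np.asarray(risk, dtype=float)
    if np.any((risk != 1) & (risk != 2)):
        raise ValueError("risk multiplier must be 1 (low) or 2 (high)")
    out = (1.0 - x ** spec.exponent) * risk
    return out if np.ndim(out) else float(out)
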