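"""Small summary formulas for reporting perturbation effects.

Condition means (from flow cytometry, densitometry, ...) are taken as inputs;
the acquisitions themselves are out of scope.
"""
from __future__ import annotations

from .errors import ValidationError


def relative_percent_reduction(treated_mean: float, control_mean: float) -> float:
    """``(1 - treated/control) * 100`` — e.g. the relative reduction of the
    S-phase cell fraction in a knockdown line versus the scramble control.

    Antitone in ``treated_mean``; 0 when treated equals control; 100 when the
    treated mean is zero.
    """
    if not control_mean > 0:
        raise ValidationError(f"control mean must be > 0, got {control_mean}")
    if treated_mean < 0:
        raise ValidationError(f"treated mean must be >= 0, got {treated_mean}")
    # (c - t) * 100 / c rather than (1 - t/c) * 100: same formula, exact for
    # decimally-printed inputs like (36, 50) -> 28.0
    return (control_mean - treated_mean) * 100.0 / control_mean


def normalized_ratio(
    numerator: float, denominator: float, reference_ratio: float
) -> float:
    """``(numerator/denominator) / reference_ratio`` — e.g. a Bax/Bcl-2
    protein ratio expressed relative to the control condition's ratio."""
    if not denominator > 0:
        raise ValidationError(f"denominator must be > 0, got {denominator}")
    if not reference_ratio > 0:
        raise ValidationError(f"reference ratio must be > 0, got {reference_ratio}")
    if numerator < 0:
        raise ValidationError(f"numerator must be >= 0, got {numerator}")
    return (numerator / denominator) / reference_ratio
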