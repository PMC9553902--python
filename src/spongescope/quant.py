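"""Relative expression quantification by the delta-delta-Ct method.

Fold change = 2^(-ddCt) with dCt = Ct(target) - Ct(reference) per condition
and ddCt = dCt(treated) - dCt(control). Amplification efficiency is fixed at
the ideal value of 2 (one doubling per cycle); a Ct above 40 cycles means the
transcript was not reliably detected and the computation refuses to proceed
rather than returning a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CtMeasurement",
    "UndetectedError",
    "delta_delta_ct",
    "fold_change_with_sd",
    "CT_DETECTION_LIMIT",
]

CT_DETECTION_LIMIT = 40.0


class UndetectedError(ValueError):
    """A Ct value beyond the detection limit; fold change is undefined."""


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR measurement: target and reference-gene Ct in the same sample."""

    target_ct: float
    reference_ct: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.target_ct) and np.isfinite(self.reference_ct)):
            raise ValueError("Ct values must be finite")

    @property
    def undetected(self) -> bool:
        return self.target_ct > CT_DETECTION_LIMIT or self.reference_ct > CT_DETECTION_LIMIT

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def delta_delta_ct(treated: CtMeasurement, control: CtMeasurement) -> float:
    """Fold change of the target in ``treated`` relative to ``control``.

    Raises :class:`UndetectedError` if either measurement has a Ct above the
    detection limit (never returns a silent 0).
    """
    for name, m in (("treated", treated), ("control", control)):
        if m.undetected:
            raise UndetectedError(
                f"{name} measurement undetected (Ct > {CT_DETECTION_LIMIT:g}); "
                "fold change undefined"
            )
    ddct = treated.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))


def fold_change_with_sd(
    treated_target_cts: Sequence[float],
    treated_reference_cts: Sequence[float],
    control_target_cts: Sequence[float],
    control_reference_cts: Sequence[float],
    condition: str = "",
) -> tuple[float, tuple[float, float]]:
    """Replicate-aware fold change: Ct replicates are averaged before ddCt.

    The replicate SD of ddCt (combined in quadrature over the four Ct series)
    is propagated as the multiplicative range
    ``[2^(-ddCt - SD), 2^(-ddCt + SD)]``.
    """
    groups = [
        np.asarray(x, dtype=float)
        for x in (
            treated_target_cts,
            treated_reference_cts,
            control_target_cts,
            control_reference_cts,
        )
    ]
    for g in groups:
        if g.size == 0:
            raise ValueError("empty Ct replicate series")
        if np.any(g > CT_DETECTION_LIMIT):
            raise UndetectedError(
                f"replicate Ct beyond detection limit ({CT_DETECTION_LIMIT:g})"
            )
    means = [float(g.mean()) for g in groups]
    treated = CtMeasurement(means[0], means[1], condition)
    control = CtMeasurement(means[2], means[3], "control")
    fold = delta_delta_ct(treated, control)
    sd = float(np.sqrt(sum(g.std(ddof=1) ** 2 if g.size > 1 else 0.0 for g in groups)))
    ddct = treated.delta_ct - control.delta_ct
    return fold, (float(2.0 ** (-ddct - sd)), float(2.0 ** (-ddct + sd)))
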