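"""Frozen model constants for the chill/heat accumulation models.

All constants are kept in this single module so that results are
bit-reproducible across installs and so that provenance is auditable in
one place.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class DynamicParams:
    """Constants of the two-step Dynamic (chill portion) model.

    The canonical Fishman/Erez formulation: an intermediate precursor pool
    relaxes toward a temperature-dependent equilibrium ``xs`` at rate
    ``ak1``; once the pool reaches ``crit`` (= 1) a temperature-dependent
    fraction ``xi`` converts irreversibly into chill portions.

    Units: ``tetmlt``, ``e0`` and ``e1`` are in Kelvin; ``slp``, ``a0``,
    ``a1`` and ``crit`` are dimensionless.  ``kelvin_offset`` is the
    Celsius-to-Kelvin shift used by the canonical hourly transcription
    (273, not 273.15 — kept verbatim for bit-compatibility with the
    reference recursion).
    """

    slp: float = 1.6
    tetmlt: float = 277.0
    e0: float = 4153.5
    e1: float = 12888.8
    a0: float = 139500.0
    a1: float = 2.567e18
    crit: float = 1.0
    kelvin_offset: float = 273.0

    def __post_init__(self) -> None:
        if not (self.e1 > self.e0 > 0 and self.a1 > self.a0 > 0):
            raise ValueError("require e1 > e0 > 0 and a1 > a0 > 0")
        if self.slp <= 0 or self.tetmlt <= 0 or self.crit <= 0:
            raise ValueError("slp, tetmlt and crit must be positive")


#: Default Dynamic-model constants.
DYNAMIC_PARAMS = DynamicParams()

#: Utah-model stepwise weights: (lower, upper, chill units per hour],
#: intervals half-open on the left, i.e. lower < T <= upper.
UTAH_WEIGHTS: tuple[tuple[float, float, float], ...] = (
    (float("-inf"), 1.4, 0.0),
    (1.4, 2.4, 0.5),
    (2.4, 9.1, 1.0),
    (9.1, 12.4, 0.5),
    (12.4, 15.9, 0.0),
    (15.9, 18.0, -0.5),
    (18.0, float("inf"), -1.0),
)

#: Weinberger chilling-hour threshold: one chill hour per hour strictly
#: below 7.2 degC (the Celsius equivalent of 45 degF).
WEINBERGER_THRESHOLD_F: float = 45.0
WEINBERGER_THRESHOLD_C: float = round((WEINBERGER_THRESHOLD_F - 32.0) * 5.0 / 9.0, 1)

#: Growing-degree-hour base and optimum (capped linear form): each hour
#: contributes max(0, min(T, GDH_CAP_C) - GDH_BASE_C) degC.h.
GDH_BASE_C: float = 4.5
GDH_CAP_C: float = 25.0
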