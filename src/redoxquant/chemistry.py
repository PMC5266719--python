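"""Bicarbonate/CO2 speciation of the treatment medium.

A bicarbonate spike in a pH-buffered medium partitions between HCO3- and
dissolved CO2 according to the Henderson-Hasselbalch relation

    pH = pK1 + log10([HCO3-] / [CO2])

with pK1 the first acid dissociation constant of carbonic acid.  Below pK1
the majority species is dissolved CO2.  For the 3 mM treatment at pH 5.8
(pK1 = 6.352) the equation yields [CO2] = 2.34 mM and [HCO3-] = 0.66 mM.
"""

from __future__ import annotations

from dataclasses import dataclass

PK1_CARBONIC_ACID = 6.352


@dataclass(frozen=True)
class CarbonateConditions:
    """Total dissolved carbonate (mM) and medium pH."""

    total_mM: float
    pH: float
    pK1: float = PK1_CARBONIC_ACID

    def __post_init__(self) -> None:
        if not self.total_mM > 0:
            raise ValueError("total carbonate must be positive")
        if not 0 < self.pH < 14:
            raise ValueError("pH out of range")


def carbonate_speciation(cond: CarbonateConditions) -> tuple[float, float]:
    """Partition total carbonate into (bicarbonate mM, dissolved CO2 mM).

    [HCO3-]/[CO2] = 10**(pH - pK1) and the two species sum to the total.

    >>> hco3, co2 = carbonate_speciation(CarbonateConditions(3.0, 5.8))
    >>> round(hco3, 2), round(co2, 2)
    (0.66, 2.34)
    """
    ratio = 10.0 ** (cond.pH - cond.pK1)
    co2 = cond.total_mM / (1.0 + ratio)
    hco3 = cond.total_mM - co2
    return hco3, co2
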