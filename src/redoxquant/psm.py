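"""Peptide-spectrum-match records carrying dual-label reporter intensities."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .design import ChannelDesign, IODO_LABELS, ITRAQ_LABELS
from .peptides import ModifiedPeptide


@dataclass(frozen=True)
class PSMRecord:
    """One identified MS/MS spectrum with its reporter-ion intensities.

    Intensities are non-negative; a channel that was not observed is simply
    absent from the mapping.  Zero intensities are treated as missing upstream
    (reporter interference makes true zeros unobservable).
    """

    peptide: ModifiedPeptide
    replicate: str
    iodo_intensities: Mapping[str, float] = field(default_factory=dict)
    itraq_intensities: Mapping[str, float] = field(default_factory=dict)
    fraction: Optional[str] = None

    def __post_init__(self) -> None:
        if not set(self.iodo_intensities) <= set(IODO_LABELS):
            raise ValueError("unknown iodoTMT reporter label")
        if not set(self.itraq_intensities) <= set(ITRAQ_LABELS):
            raise ValueError("unknown iTRAQ reporter label")
        for mapping in (self.iodo_intensities, self.itraq_intensities):
            for label, value in mapping.items():
                if not value > 0:
                    raise ValueError(
                        f"channel {label}: intensity must be positive, got {value}"
                    )
        if not self.itraq_intensities:
            raise ValueError("a PSM needs at least one iTRAQ reporter intensity")


@dataclass(frozen=True)
class PSMSet:
    """A collection of PSMs together with the channel design that produced them."""

    records: tuple[PSMRecord, ...]
    design: ChannelDesign

    def __post_init__(self) -> None:
        known = set(self.design.replicates)
        for rec in self.records:
            if rec.replicate not in known:
                raise ValueError(
                    f"replicate {rec.replicate!r} not declared in the design"
                )

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: one row per PSM, one column per reporter channel.

        Missing channels are NaN.  Columns: ``peptide`` (annotated string),
        ``accessions``, ``replicate``, ``fraction``, ``iodo_126``..``iodo_131``,
        ``itraq_113``..``itraq_118``.
        """
        from .peptides import render_modified_sequence

        rows = []
        for rec in self.records:
            row: dict = {
                "peptide": render_modified_sequence(rec.peptide),
                "accessions": ";".join(rec.peptide.accessions),
                "replicate": rec.replicate,
                "fraction": rec.fraction if rec.fraction is not None else "",
            }
            for label in IODO_LABELS:
                row[f"iodo_{label}"] = rec.iodo_intensities.get(label)
            for label in ITRAQ_LABELS:
                row[f"itraq_{label}"] = rec.itraq_intensities.get(label)
            rows.append(row)
        return pd.DataFrame(rows, columns=_COLUMNS)


_COLUMNS = (
    ["peptide", "accessions", "replicate", "fraction"]
    + [f"iodo_{label}" for label in IODO_LABELS]
    + [f"itraq_{label}" for label in ITRAQ_LABELS]
)
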