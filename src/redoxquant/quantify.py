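"""Reporter-intensity normalization, ratio computation, and protein rollup.

All operations work per biological replicate: each replicate is an independent
6-plex labeling run, so intensity scales are not comparable across replicates
and every scaling factor is derived within one replicate only.

The two label spaces are normalized the way the originating workflow
describes them:

* iodoTMT (Cys redox): per-channel median equalization over unique, labeled
  cysteine peptides;
* iTRAQ (protein abundance): each channel's unique-peptide total is scaled to
  the channel-113 total, then peptides are rolled up to proteins by a median
  over (PSM-summed) peptide values.

Treated/control fold changes are taken per timepoint from the channel design,
and a second normalization rescales every (replicate, timepoint) slice of
fold changes to median 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ChannelDesign, IODO_LABELS, ITRAQ_LABELS
from .peptides import render_modified_sequence
from .psm import PSMSet


class NormalizationError(ValueError):
    pass


@dataclass
class IntensityMatrix:
    """Entities x (replicate, channel) intensities with normalization provenance.

    ``values`` is indexed by (peptide, accession) before protein rollup and by
    accession after; columns are a (replicate, label) MultiIndex; missing
    observations are NaN.
    """

    values: pd.DataFrame
    space: str  # "iodo" | "itraq"
    provenance: str
    flags: list[str] = field(default_factory=list)


@dataclass
class RatioMatrix:
    """Entity x (timepoint, replicate) linear treated/control fold changes."""

    values: pd.DataFrame
    level: str  # "iodoTMT-peptide" | "iTRAQ-protein"
    flags: list[str] = field(default_factory=list)


def summed_peptide_matrix(psmset: PSMSet, space: str) -> pd.DataFrame:
    """Sum repeated PSMs of each unique peptide per channel and replicate.

    Only unique peptides (single protein accession) enter quantification; for
    the iodoTMT space the peptide must additionally carry an iodoTMT label.
    Index: (annotated peptide, accession); columns: (replicate, label).
    """
    labels = IODO_LABELS if space == "iodo" else ITRAQ_LABELS
    rows = []
    for rec in psmset.records:
        pep = rec.peptide
        if not pep.is_unique:
            continue
        if space == "iodo" and not pep.is_iodo_labeled:
            continue
        intens = rec.iodo_intensities if space == "iodo" else rec.itraq_intensities
        if not intens:
            continue
        row = {
            "peptide": render_modified_sequence(pep),
            "accession": pep.accessions[0],
            "replicate": rec.replicate,
        }
        row.update({label: intens.get(label, np.nan) for label in labels})
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            index=pd.MultiIndex.from_tuples([], names=["peptide", "accession"]),
            columns=pd.MultiIndex.from_tuples([], names=["replicate", "label"]),
        )
    long = pd.DataFrame(rows)
    summed = long.groupby(["peptide", "accession", "replicate"])[list(labels)].sum(
        min_count=1
    )
    wide = summed.unstack("replicate")  # columns: (label, replicate)
    wide.columns = wide.columns.swaplevel(0, 1)
    wide.columns.names = ["replicate", "label"]
    replicates = [r for r in psmset.design.replicates if r in wide.columns.levels[0]]
    wide = wide.reindex(
        columns=pd.MultiIndex.from_product(
            [replicates, list(labels)], names=["replicate", "label"]
        )
    )
    return wide.sort_index()


def median_normalize_iodo(psmset: PSMSet) -> IntensityMatrix:
    """Equalize the six iodoTMT channel medians within each replicate.

    Each channel is scaled so its median over unique labeled peptides equals
    the grand median of the six pre-normalization channel medians.  A channel
    with no observations in a replicate is left unscaled and flagged.
    """
    values = summed_peptide_matrix(psmset, "iodo")
    if values.empty:
        raise NormalizationError("no unique iodoTMT-labeled cysteine peptides")
    flags: list[str] = []
    out = values.copy()
    for replicate in values.columns.get_level_values("replicate").unique():
        block = values[replicate]
        medians = block.median(axis=0, skipna=True)
        if medians.isna().any():
            for label in medians.index[medians.isna()]:
                msg = f"iodo channel {label} entirely missing in {replicate}"
                warnings.warn(msg)
                flags.append(f"unscaled:{replicate}:{label}")
        grand = medians.dropna().median()
        factors = grand / medians
        factors = factors.fillna(1.0)
        out[replicate] = block * factors
    return IntensityMatrix(out, "iodo", "median_normalize_iodo", flags)


def normalize_itraq(psmset: PSMSet) -> IntensityMatrix:
    """Scale each iTRAQ channel's total to the channel-113 total per replicate.

    Totals are taken over unique peptides observed in channel 113 in that
    replicate; the resulting factor is applied to the whole channel.
    """
    values = summed_peptide_matrix(psmset, "itraq")
    if values.empty:
        raise NormalizationError("no unique peptides with iTRAQ intensities")
    out = values.copy()
    for replicate in values.columns.get_level_values("replicate").unique():
        block = values[replicate]
        anchored = block[block["113"].notna()]
        if anchored.empty:
            raise NormalizationError(
                f"no peptides observed in channel 113 in replicate {replicate}"
            )
        totals = anchored.sum(axis=0, skipna=True)
        if (totals == 0).any() or totals.isna().any():
            bad = [str(c) for c in totals.index[(totals == 0) | totals.isna()]]
            raise NormalizationError(
                f"zero total in iTRAQ channel(s) {bad} in replicate {replicate}"
            )
        out[replicate] = block * (totals["113"] / totals)
    return IntensityMatrix(out, "itraq", "normalize_itraq")


def group_proteins(matrix: IntensityMatrix) -> IntensityMatrix:
    """Roll peptide intensities up to proteins.

    Per protein and channel: the median over its peptides' PSM-summed
    intensities, skipping unobserved cells.  Single-peptide proteins keep the
    peptide's value.
    """
    grouped = matrix.values.groupby(level="accession").median()
    return IntensityMatrix(
        grouped, matrix.space, matrix.provenance + "+group_proteins", list(matrix.flags)
    )


def compute_ratios(matrix: IntensityMatrix, design: ChannelDesign) -> RatioMatrix:
    """Treated/control fold change per entity, replicate and timepoint.

    The control/treated channel pairing comes from the design (default iodoTMT
    pairs 127/126, 129/128, 131/130 at 5/30/120 min; iTRAQ pairs 114/113,
    116/115, 118/117).  A ratio is missing wherever either side is missing or
    the control intensity is non-positive (flagged).
    """
    flags = list(matrix.flags)
    pieces = {}
    replicates = matrix.values.columns.get_level_values("replicate").unique()
    for tp in design.timepoints:
        control, treated = design.pair(matrix.space, tp)
        for replicate in replicates:
            block = matrix.values[replicate]
            num = block[treated]
            den = block[control]
            bad = den.notna() & (den <= 0)
            if bad.any():
                flags.append(f"nonpositive-control:{replicate}:tp{tp}")
                den = den.mask(bad)
            pieces[(tp, replicate)] = num / den
    values = pd.DataFrame(pieces)
    values.columns.names = ["timepoint", "replicate"]
    level = "iodoTMT-peptide" if matrix.space == "iodo" else "iTRAQ-protein"
    return RatioMatrix(values, level, flags)


def renormalize_ratios(ratios: RatioMatrix) -> RatioMatrix:
    """Rescale each (timepoint, replicate) slice of fold changes to median 1."""
    if ratios.values.empty:
        raise NormalizationError("empty ratio matrix")
    out = ratios.values.copy()
    flags = list(ratios.flags)
    for col in out.columns:
        med = out[col].median(skipna=True)
        if not np.isfinite(med) or med <= 0:
            warnings.warn(f"ratio slice {col} has no usable median; left unscaled")
            flags.append(f"unrenormalized:{col}")
            continue
        out[col] = out[col] / med
    return RatioMatrix(out, ratios.level, flags)
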