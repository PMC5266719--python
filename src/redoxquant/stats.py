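"""Significance testing on log2 fold changes and the redox-vs-abundance call.

A cysteine peptide's iodoTMT fold change confounds thiol oxidation with any
change in the parent protein's abundance.  The classification therefore
combines three tests per timepoint:

1. one-sample two-tailed t-test of the peptide's replicate log2 iodoTMT fold
   changes against 0;
2. the same test on the parent protein's iTRAQ fold changes;
3. a two-sample t-test between the peptide and protein log2 fold changes,
   asking whether the cysteine signal exceeds what abundance alone explains.

A peptide is *redox_responsive* when at least one significant iodoTMT
timepoint is not explained by a same-direction significant protein change,
*abundance_driven* when every significant timepoint is so explained, and
*unchanged* otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

UNCHANGED = "unchanged"
REDOX_RESPONSIVE = "redox_responsive"
ABUNDANCE_DRIVEN = "abundance_driven"

# spread (log2 scale) below which a sample is treated as zero-variance;
# normalization arithmetic leaves ulp-level jitter on identical ratios, far
# below any real reporter-ion noise
_DEGENERATE_SPREAD = 1e-9


@dataclass(frozen=True)
class TestResult:
    """One entity/timepoint significance test on replicate fold changes."""

    entity: str
    timepoint: int
    n: int
    mean_fc: Optional[float]
    mean_log2_fc: Optional[float]
    p_value: Optional[float]
    flags: tuple[str, ...] = ()

    def significant(self, alpha: float, min_reps: int) -> bool:
        return (
            self.p_value is not None
            and self.p_value < alpha
            and self.n >= min_reps
        )


def log_ratio_t_test(
    fcs: Sequence[float], entity: str = "", timepoint: int = 0
) -> TestResult:
    """One-sample two-tailed t-test of log2(FC) against 0.

    With fewer than two finite fold changes the p-value is undefined.  A
    zero-variance sample cannot support a t statistic; it is reported with
    p = 1 and a ``degenerate-variance`` flag rather than p = 0, so duplicated
    or saturated values never create spurious significance.
    """
    values = np.asarray([fc for fc in fcs if fc is not None and np.isfinite(fc)])
    if values.size and (values <= 0).any():
        raise ValueError("fold changes must be positive")
    if values.size == 0:
        return TestResult(entity, timepoint, 0, None, None, None, ("no-data",))
    logs = np.log2(values)
    mean_fc = float(np.mean(values))
    mean_log = float(np.mean(logs))
    if values.size < 2:
        return TestResult(
            entity, timepoint, 1, mean_fc, mean_log, None, ("insufficient-replicates",)
        )
    if np.ptp(logs) < _DEGENERATE_SPREAD:
        if abs(mean_log) < _DEGENERATE_SPREAD:
            return TestResult(entity, timepoint, values.size, mean_fc, mean_log, 1.0)
        return TestResult(
            entity, timepoint, values.size, mean_fc, mean_log, 1.0,
            ("degenerate-variance",),
        )
    t, p = sps.ttest_1samp(logs, popmean=0.0)
    return TestResult(entity, timepoint, values.size, mean_fc, mean_log, float(p))


def peptide_vs_protein_test(
    peptide_log2_fcs: Sequence[float],
    protein_log2_fcs: Sequence[float],
    equal_var: bool = True,
) -> tuple[Optional[float], tuple[str, ...]]:
    """Two-sample two-tailed t-test between peptide and protein log2 FCs.

    Equal variances are pooled by default (Student's test); with n = 3 per
    side there is little basis for estimating separate variances, but the
    Welch form is available via ``equal_var=False``.  Returns (p, flags); p
    is None with fewer than two replicates on either side.  Zero pooled
    variance gives p = 1 when the means coincide and p = 1 with a degenerate
    flag otherwise (conservative, mirroring the one-sample convention).
    """
    a = np.asarray([v for v in peptide_log2_fcs if v is not None and np.isfinite(v)])
    b = np.asarray([v for v in protein_log2_fcs if v is not None and np.isfinite(v)])
    if a.size < 2 or b.size < 2:
        return None, ("insufficient-replicates",)
    if np.ptp(a) < _DEGENERATE_SPREAD and np.ptp(b) < _DEGENERATE_SPREAD:
        if abs(a.mean() - b.mean()) < _DEGENERATE_SPREAD:
            return 1.0, ()
        return 1.0, ("degenerate-variance",)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(p), ()


@dataclass(frozen=True)
class RedoxCall:
    """Per-peptide verdict combining iodoTMT and iTRAQ evidence."""

    peptide: str
    accession: str
    cys_positions: tuple[int, ...]
    iodo_results: Mapping[int, TestResult]
    itraq_results: Mapping[int, TestResult]
    comparison_p: Mapping[int, Optional[float]]
    label: str
    flags: frozenset[str] = frozenset()


def classify(
    peptide_results: Mapping[int, TestResult],
    protein_results: Mapping[int, TestResult],
    comparison_p: Mapping[int, Optional[float]],
    *,
    peptide: str = "",
    accession: str = "",
    cys_positions: tuple[int, ...] = (),
    alpha: float = 0.05,
    min_reps: int = 2,
) -> RedoxCall:
    """Label one cysteine peptide as redox, abundance-driven, or unchanged.

    A significant iodoTMT timepoint is *explained by abundance* when the
    protein change at that timepoint is significant, in the same direction
    (matching sign of the mean log2 FC), and the peptide-vs-protein test is
    not significant.  Undefined p-values count as non-significant and are
    flagged.
    """
    if set(peptide_results) != set(protein_results):
        raise ValueError("peptide and protein results must share timepoints")
    flags: set[str] = set()
    significant_tps = []
    for tp, res in peptide_results.items():
        if res.p_value is None:
            flags.add(f"undefined-iodo-p:tp{tp}")
        if res.significant(alpha, min_reps):
            significant_tps.append(tp)
    for tp, res in protein_results.items():
        if res.significant(alpha, min_reps):
            flags.add("protein-level-change-detected")

    if not significant_tps:
        label = UNCHANGED
    else:
        explained = []
        for tp in significant_tps:
            pep = peptide_results[tp]
            prot = protein_results[tp]
            cmp_p = comparison_p.get(tp)
            if cmp_p is None:
                flags.add(f"undefined-comparison-p:tp{tp}")
            prot_significant = prot.significant(alpha, min_reps)
            same_direction = (
                prot.mean_log2_fc is not None
                and pep.mean_log2_fc is not None
                and math.copysign(1, pep.mean_log2_fc)
                == math.copysign(1, prot.mean_log2_fc)
            )
            comparison_significant = cmp_p is not None and cmp_p < alpha
            explained.append(
                prot_significant and same_direction and not comparison_significant
            )
        label = ABUNDANCE_DRIVEN if all(explained) else REDOX_RESPONSIVE

    return RedoxCall(
        peptide=peptide,
        accession=accession,
        cys_positions=cys_positions,
        iodo_results=dict(peptide_results),
        itraq_results=dict(protein_results),
        comparison_p=dict(comparison_p),
        label=label,
        flags=frozenset(flags),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out
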