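"""Model/Results interface for the dual-label redox discovery analysis.

Usage follows the fit-then-inspect convention of statistical modelling
packages::

    model = RedoxQuantModel(psmset)
    results = model.fit(alpha=0.05, min_reps=2)
    print(results.summary())
    results.to_results_table("calls.tsv")
    tree = results.cluster_tree(k=2)

The model owns the quantification pipeline (normalization, ratio
computation, protein rollup); ``fit`` runs the per-timepoint tests and the
redox-vs-abundance classification and returns a results object carrying the
calls, the intermediate ratio matrices, and the attrition summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import cluster as _cluster
from .design import ChannelDesign
from .io import read_psm_table, write_results_table
from .peptides import parse_modified_sequence
from .psm import PSMSet
from .quantify import (
    RatioMatrix,
    compute_ratios,
    group_proteins,
    median_normalize_iodo,
    normalize_itraq,
    renormalize_ratios,
)
from .stats import (
    ABUNDANCE_DRIVEN,
    REDOX_RESPONSIVE,
    UNCHANGED,
    RedoxCall,
    TestResult,
    benjamini_hochberg,
    classify,
    log_ratio_t_test,
    peptide_vs_protein_test,
)


def run_discovery(
    psmset: PSMSet, alpha: float = 0.05, min_reps: int = 2, **fit_kwargs
) -> "RedoxQuantResults":
    """One-call discovery: quantify, test, and classify a PSM set.

    Convenience wrapper over ``RedoxQuantModel(psmset).fit(...)``.
    """
    return RedoxQuantModel(psmset).fit(alpha=alpha, min_reps=min_reps, **fit_kwargs)


def label_rate_percent(n_labeled: int, n_cys_peptides: int) -> int:
    """Labeled fraction of cysteine peptides, as a rounded integer percent."""
    if n_cys_peptides == 0:
        return 0
    return int(round(100.0 * n_labeled / n_cys_peptides))


class RedoxQuantModel:
    """Dual-label (iodoTMT + iTRAQ) redox discovery model over a PSM set."""

    def __init__(
        self,
        psmset: PSMSet,
        *,
        renormalize_iodo: bool = True,
        renormalize_itraq: bool = True,
    ) -> None:
        self.psmset = psmset
        self.design = psmset.design
        self.renormalize_iodo = renormalize_iodo
        self.renormalize_itraq = renormalize_itraq

    @classmethod
    def from_tables(
        cls, psm_path: str, design: Union[ChannelDesign, str, None] = None, **kwargs
    ) -> "RedoxQuantModel":
        """Build the model from a PSM TSV and a channel design (object, YAML
        path, or None for the default layout)."""
        if design is None:
            design = ChannelDesign.default()
        elif isinstance(design, str):
            from .design import read_design

            design = read_design(design)
        return cls(read_psm_table(psm_path, design), **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        min_reps: int = 2,
        *,
        bh: bool = False,
        welch: bool = False,
    ) -> "RedoxQuantResults":
        """Quantify, test, and classify every labeled cysteine peptide.

        Parameters
        ----------
        alpha : significance threshold for all three tests.
        min_reps : minimum replicates with an observed ratio for a timepoint
            to count as significant (the "present in at least two biological
            replicates" rule).
        bh : apply Benjamini-Hochberg adjustment to the iodoTMT and iTRAQ
            p-values (off by default; the discovery convention is raw p).
        welch : use the unequal-variance form of the peptide-vs-protein test.
        """
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        design = self.design
        timepoints = design.timepoints

        counts = self._attrition_counts()

        iodo_norm = median_normalize_iodo(self.psmset)
        iodo_ratios = compute_ratios(iodo_norm, design)
        if self.renormalize_iodo:
            iodo_ratios = renormalize_ratios(iodo_ratios)

        itraq_norm = normalize_itraq(self.psmset)
        protein_values = group_proteins(itraq_norm)
        itraq_ratios = compute_ratios(protein_values, design)
        if self.renormalize_itraq:
            itraq_ratios = renormalize_ratios(itraq_ratios)

        protein_tests = self._protein_tests(itraq_ratios, timepoints)

        # per-timepoint numpy views (rows aligned with the ratio index) keep
        # the per-peptide loop free of repeated pandas label lookups
        iodo_by_tp = {
            tp: iodo_ratios.values.xs(tp, axis=1, level="timepoint").to_numpy()
            for tp in timepoints
        }
        itraq_by_tp = {
            tp: itraq_ratios.values.xs(tp, axis=1, level="timepoint").to_numpy()
            for tp in timepoints
        }
        protein_row = {
            acc: i for i, acc in enumerate(itraq_ratios.values.index)
        }
        peptide_index = list(iodo_ratios.values.index)

        iodo_results: dict[tuple[str, str], dict[int, TestResult]] = {}
        for i, (peptide, accession) in enumerate(peptide_index):
            per_tp = {}
            for tp in timepoints:
                row = iodo_by_tp[tp][i]
                per_tp[tp] = log_ratio_t_test(row[~np.isnan(row)], peptide, tp)
            iodo_results[(peptide, accession)] = per_tp

        if bh:
            self._adjust_pvalues(iodo_results)
            self._adjust_pvalues(protein_tests)

        calls: list[RedoxCall] = []
        for i, (peptide, accession) in enumerate(peptide_index):
            per_tp = iodo_results[(peptide, accession)]
            prot_per_tp = protein_tests.get(accession)
            if prot_per_tp is None:
                prot_per_tp = {
                    tp: TestResult(accession, tp, 0, None, None, None, ("no-data",))
                    for tp in timepoints
                }
            comparison: dict[int, Optional[float]] = {}
            for tp in timepoints:
                pep_row = iodo_by_tp[tp][i]
                pep_fcs = pep_row[~np.isnan(pep_row)]
                if accession in protein_row:
                    prot_row = itraq_by_tp[tp][protein_row[accession]]
                    prot_fcs = prot_row[~np.isnan(prot_row)]
                else:
                    prot_fcs = np.empty(0)
                p, _ = peptide_vs_protein_test(
                    np.log2(pep_fcs),
                    np.log2(prot_fcs),
                    equal_var=not welch,
                )
                comparison[tp] = p
            parsed = parse_modified_sequence(peptide, [accession])
            calls.append(
                classify(
                    per_tp,
                    prot_per_tp,
                    comparison,
                    peptide=peptide,
                    accession=accession,
                    cys_positions=parsed.labeled_cys_positions,
                    alpha=alpha,
                    min_reps=min_reps,
                )
            )
        calls.sort(key=lambda c: (c.accession, c.peptide))
        return RedoxQuantResults(
            model=self,
            calls=tuple(calls),
            iodo_ratios=iodo_ratios,
            itraq_ratios=itraq_ratios,
            alpha=alpha,
            min_reps=min_reps,
            attrition=counts,
        )

    def _attrition_counts(self) -> dict[str, int]:
        peptide_keys = set()
        unique_keys = set()
        cys_keys = set()
        labeled_keys = set()
        proteins = set()
        for rec in self.psmset.records:
            key = rec.peptide.key()
            peptide_keys.add(key)
            if rec.peptide.is_unique:
                unique_keys.add(key)
                proteins.add(rec.peptide.accessions[0])
            if rec.peptide.is_cysteine_containing:
                cys_keys.add(key)
                if rec.peptide.is_iodo_labeled:
                    labeled_keys.add(key)
        return {
            "n_psms": len(self.psmset),
            "n_peptides": len(peptide_keys),
            "n_unique_peptides": len(unique_keys),
            "n_proteins": len(proteins),
            "n_cys_peptides": len(cys_keys),
            "n_labeled_peptides": len(labeled_keys),
            "label_rate_percent": label_rate_percent(len(labeled_keys), len(cys_keys)),
        }

    def _protein_tests(
        self, itraq_ratios: RatioMatrix, timepoints
    ) -> dict[str, dict[int, TestResult]]:
        out: dict[str, dict[int, TestResult]] = {}
        by_tp = {
            tp: itraq_ratios.values.xs(tp, axis=1, level="timepoint").to_numpy()
            for tp in timepoints
        }
        for i, accession in enumerate(itraq_ratios.values.index):
            per_tp = {}
            for tp in timepoints:
                row = by_tp[tp][i]
                per_tp[tp] = log_ratio_t_test(row[~np.isnan(row)], accession, tp)
            out[accession] = per_tp
        return out

    @staticmethod
    def _adjust_pvalues(results: dict) -> None:
        keyed = [
            (key, tp)
            for key, per_tp in results.items()
            for tp, res in per_tp.items()
            if res.p_value is not None
        ]
        if not keyed:
            return
        raw = [results[key][tp].p_value for key, tp in keyed]
        adjusted = benjamini_hochberg(raw)
        for (key, tp), p_adj in zip(keyed, adjusted):
            res = results[key][tp]
            results[key][tp] = TestResult(
                res.entity, res.timepoint, res.n, res.mean_fc, res.mean_log2_fc,
                float(p_adj), res.flags + ("bh-adjusted",),
            )


@dataclass
class RedoxQuantResults:
    """Fitted discovery results: per-peptide calls plus diagnostics."""

    model: RedoxQuantModel
    calls: tuple[RedoxCall, ...]
    iodo_ratios: RatioMatrix
    itraq_ratios: RatioMatrix
    alpha: float
    min_reps: int
    attrition: dict[str, int]

    @property
    def label_counts(self) -> dict[str, int]:
        counts = {UNCHANGED: 0, REDOX_RESPONSIVE: 0, ABUNDANCE_DRIVEN: 0}
        for call in self.calls:
            counts[call.label] += 1
        return counts

    def significant_per_timepoint(self) -> dict[int, int]:
        out = {tp: 0 for tp in self.model.design.timepoints}
        for call in self.calls:
            for tp, res in call.iodo_results.items():
                if res.significant(self.alpha, self.min_reps):
                    out[tp] += 1
        return out

    def summary_counts(self) -> dict:
        """JSON-ready summary: identification funnel and per-label tallies."""
        return {
            **self.attrition,
            "n_tested_peptides": len(self.calls),
            "alpha": self.alpha,
            "min_reps": self.min_reps,
            "labels": self.label_counts,
            "significant_iodo_per_timepoint": {
                str(tp): n for tp, n in self.significant_per_timepoint().items()
            },
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        a = self.attrition
        labels = self.label_counts
        lines = [
            "Dual-label redox discovery summary",
            "=" * 42,
            f"PSMs read                 {a['n_psms']:>8}",
            f"distinct peptides         {a['n_peptides']:>8}",
            f"unique (single-protein)   {a['n_unique_peptides']:>8}",
            f"proteins                  {a['n_proteins']:>8}",
            f"Cys-containing peptides   {a['n_cys_peptides']:>8}",
            f"iodoTMT-labeled peptides  {a['n_labeled_peptides']:>8}"
            f"  ({a['label_rate_percent']}%)",
            f"tested (quantified)       {len(self.calls):>8}",
            "-" * 42,
            f"alpha = {self.alpha}, min replicates = {self.min_reps}",
            f"redox_responsive          {labels[REDOX_RESPONSIVE]:>8}",
            f"abundance_driven          {labels[ABUNDANCE_DRIVEN]:>8}",
            f"unchanged                 {labels[UNCHANGED]:>8}",
        ]
        return "\n".join(lines)

    def to_results_table(self, target) -> None:
        write_results_table(self.calls, target)

    def write_summary_json(self, target) -> None:
        if isinstance(target, str):
            with open(target, "w") as fh:
                json.dump(self.summary_counts(), fh, indent=2, sort_keys=True)
                fh.write("\n")
        else:
            json.dump(self.summary_counts(), target, indent=2, sort_keys=True)

    def significant_calls(self) -> tuple[RedoxCall, ...]:
        return tuple(c for c in self.calls if c.label != UNCHANGED)

    def profile_matrix(self, which: str = "significant") -> pd.DataFrame:
        """Log2 iodoTMT fold-change profiles for clustering.

        ``which``: 'significant' (default), 'redox', or 'all'.
        """
        if which == "all":
            calls: Sequence[RedoxCall] = self.calls
        elif which == "redox":
            calls = [c for c in self.calls if c.label == REDOX_RESPONSIVE]
        else:
            calls = self.significant_calls()
        return _cluster.log2_profile_matrix(calls)

    def cluster_tree(
        self,
        which: str = "significant",
        distance: str = "uncentered",
        linkage: str = "average",
    ) -> _cluster.ClusterTree:
        return _cluster.hierarchical_cluster(
            self.profile_matrix(which), distance=distance, linkage=linkage
        )
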