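"""Normalization, ratio, and protein-rollup arithmetic against hand oracles."""

import numpy as np
import pandas as pd
import pytest

from redoxquant.design import ChannelDesign
from redoxquant.psm import PSMSet
from redoxquant.quantify import (
    NormalizationError,
    compute_ratios,
    group_proteins,
    median_normalize_iodo,
    normalize_itraq,
    renormalize_ratios,
    summed_peptide_matrix,
)

from conftest import make_record

IODO = ("126", "127", "128", "129", "130", "131")
ITRAQ = ("113", "114", "115", "116", "117", "118")


def build_psmset(design, iodo_rows=None, itraq_rows=None, replicate="rep1"):
    """One record per row; iodo_rows/itraq_rows map peptide -> 6 intensities."""
    records = []
    peptides = set()
    if iodo_rows:
        peptides |= set(iodo_rows)
    if itraq_rows:
        peptides |= set(itraq_rows)
    for i, annotated in enumerate(sorted(peptides)):
        iodo = (
            dict(zip(IODO, map(float, iodo_rows[annotated])))
            if iodo_rows and annotated in iodo_rows
            else {}
        )
        itraq = (
            dict(zip(ITRAQ, map(float, itraq_rows[annotated])))
            if itraq_rows and annotated in itraq_rows
            else {label: 1000.0 for label in ITRAQ}
        )
        iodo = {k: v for k, v in iodo.items() if v > 0}
        itraq = {k: v for k, v in itraq.items() if v > 0}
        records.append(make_record(annotated, [f"P{i+1}"], replicate, iodo, itraq))
    return PSMSet(records=tuple(records), design=design)


def random_psmset(design, n_peptides, rng, with_iodo=True):
    iodo_rows = {}
    itraq_rows = {}
    for i in range(n_peptides):
        annotated = f"aVLcDE{_suffix(i)}K"
        if with_iodo:
            iodo_rows[annotated] = rng.uniform(100, 5000, 6)
        itraq_rows[annotated] = rng.uniform(100, 5000, 6)
    return build_psmset(design, iodo_rows, itraq_rows)


def _suffix(i):
    letters = "ADEFGHILNPQVW"
    return letters[i // len(letters)] + letters[i % len(letters)]


class TestMedianNormalizeIodo:
    def test_two_channel_hand_oracle(self, design):
        # channel 127 carries doubled intensities; its median (40) must be
        # scaled to the shared median of the others
        iodo_rows = {
            "aVLcAAAAAK": [10, 20, 10, 10, 10, 10],
            "aVLcAAAADK": [20, 40, 20, 20, 20, 20],
            "aVLcAAAAEK": [30, 60, 30, 30, 30, 30],
        }
        matrix = median_normalize_iodo(build_psmset(design, iodo_rows)).values["rep1"]
        # channel medians: five at 20, one at 40 -> grand median 20
        assert matrix["127"].median() == pytest.approx(20.0)
        assert list(matrix["127"]) == pytest.approx([10.0, 20.0, 30.0])
        assert list(matrix["126"]) == pytest.approx([10.0, 20.0, 30.0])

    def test_identical_channels_identity(self, design):
        iodo_rows = {f"aVLcAAA{c}DK": [10 * k] * 6 for k, c in enumerate("DEF", 1)}
        before = build_psmset(design, iodo_rows)
        after = median_normalize_iodo(before).values["rep1"]
        assert np.allclose(after.to_numpy(), summed_peptide_matrix(before, "iodo")["rep1"].to_numpy())

    def test_channel_medians_equalized_on_random_data(self, design):
        rng = np.random.default_rng(11)
        psmset = random_psmset(design, 20, rng)
        matrix = median_normalize_iodo(psmset).values["rep1"]
        medians = matrix.median(axis=0)
        assert np.all(np.abs(medians / medians.iloc[0] - 1) < 1e-9)

    def test_missing_channel_flagged_not_fatal(self, design):
        iodo_rows = {
            "aVLcAAAADK": [10, 20, 10, 10, 10, 0],
            "aVLcAAAAEK": [30, 60, 30, 30, 30, 0],
        }
        with pytest.warns(UserWarning, match="131"):
            result = median_normalize_iodo(build_psmset(design, iodo_rows))
        assert any("131" in flag for flag in result.flags)

    def test_repeated_psms_summed_before_median(self, design):
        records = [
            make_record("aVLcAAAADK", ["P1"], "rep1",
                        dict(zip(IODO, [10.0] * 6)), dict(zip(ITRAQ, [5.0] * 6))),
            make_record("aVLcAAAADK", ["P1"], "rep1",
                        dict(zip(IODO, [30.0] * 6)), dict(zip(ITRAQ, [5.0] * 6))),
            make_record("aVLcAAAAEK", ["P2"], "rep1",
                        dict(zip(IODO, [20.0] * 6)), dict(zip(ITRAQ, [5.0] * 6))),
        ]
        psmset = PSMSet(records=tuple(records), design=design)
        summed = summed_peptide_matrix(psmset, "iodo")["rep1"]
        assert summed.loc[("aVLcAAAADK", "P1"), "126"] == 40.0


class TestNormalizeItraq:
    def test_doubled_channel_halved(self, design):
        itraq_rows = {
            "aVLcAAAADK": [10, 20, 10, 10, 10, 10],
            "aVLcAAAAEK": [30, 60, 30, 30, 30, 30],
        }
        matrix = normalize_itraq(build_psmset(design, itraq_rows=itraq_rows)).values["rep1"]
        assert list(matrix["114"]) == pytest.approx([10.0, 30.0])

    def test_equal_totals_identity(self, design):
        itraq_rows = {
            "aVLcAAAADK": [10, 30, 25, 10, 35, 15],
            "aVLcAAAAEK": [30, 10, 15, 30, 5, 25],
        }
        psmset = build_psmset(design, itraq_rows=itraq_rows)
        matrix = normalize_itraq(psmset).values["rep1"]
        assert np.allclose(
            matrix.to_numpy(), summed_peptide_matrix(psmset, "itraq")["rep1"].to_numpy()
        )

    def test_totals_anchored_to_113_on_random_data(self, design):
        rng = np.random.default_rng(13)
        psmset = random_psmset(design, 25, rng, with_iodo=False)
        matrix = normalize_itraq(psmset).values["rep1"]
        totals = matrix.sum(axis=0)
        assert np.all(np.abs(totals / totals["113"] - 1) < 1e-9)

    def test_no_113_peptides_is_error(self, design):
        itraq_rows = {"aVLcAAAADK": [0, 20, 10, 10, 10, 10]}
        with pytest.raises(NormalizationError, match="113"):
            normalize_itraq(build_psmset(design, itraq_rows=itraq_rows))


class TestGroupProteins:
    def test_median_of_two_peptides(self, design):
        records = [
            make_record("aVLAAAAADK", ["P1"], "rep1", {}, dict(zip(ITRAQ, [30.0] * 6))),
            make_record("aVLAAAAAEK", ["P1"], "rep1", {}, dict(zip(ITRAQ, [40.0] * 6))),
            make_record("aVLAAAAAFK", ["P2"], "rep1", {}, dict(zip(ITRAQ, [7.0] * 6))),
        ]
        psmset = PSMSet(records=tuple(records), design=design)
        matrix = group_proteins(normalize_itraq(psmset))
        block = matrix.values["rep1"]
        assert block.loc["P1", "113"] == pytest.approx(35.0)
        assert block.loc["P2", "113"] == pytest.approx(7.0)  # single peptide: identity

    def test_matches_brute_force_on_random_assignment(self, design):
        rng = np.random.default_rng(17)
        records = []
        assignment = {}
        for i in range(50):
            annotated = f"aVLDE{_suffix(i)}K"
            protein = f"P{int(rng.integers(1, 11))}"
            assignment.setdefault(protein, []).append(annotated)
            intensities = dict(zip(ITRAQ, rng.uniform(100, 5000, 6)))
            records.append(make_record(annotated, [protein], "rep1", {}, intensities))
        from redoxquant.quantify import IntensityMatrix

        psmset = PSMSet(records=tuple(records), design=design)
        summed = summed_peptide_matrix(psmset, "itraq")
        grouped = group_proteins(IntensityMatrix(summed, "itraq", "raw")).values["rep1"]
        for protein, peptides in assignment.items():
            for label in ITRAQ:
                expected = np.median(
                    [summed.loc[(p, protein), ("rep1", label)] for p in peptides]
                )
                assert grouped.loc[protein, label] == pytest.approx(expected)

    def test_permutation_invariant(self, design):
        rng = np.random.default_rng(19)
        rows = []
        for i in range(12):
            rows.append(
                make_record(
                    f"aVLDE{_suffix(i)}K", [f"P{i % 4}"], "rep1", {},
                    dict(zip(ITRAQ, rng.uniform(100, 5000, 6))),
                )
            )
        forward = PSMSet(records=tuple(rows), design=design)
        backward = PSMSet(records=tuple(reversed(rows)), design=design)
        a = group_proteins(normalize_itraq(forward)).values
        b = group_proteins(normalize_itraq(backward)).values
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestComputeRatios:
    def test_glp_magnitude(self, design):
        iodo_rows = {
            "aVLcAAAADK": [1000, 280, 1000, 1000, 1000, 1000],
            "aVLcAAAAEK": [1000, 1000, 1000, 1000, 1000, 1000],
        }
        psmset = build_psmset(design, iodo_rows)
        matrix = summed_peptide_matrix(psmset, "iodo")
        from redoxquant.quantify import IntensityMatrix

        ratios = compute_ratios(IntensityMatrix(matrix, "iodo", "raw"), design)
        assert ratios.values.loc[("aVLcAAAADK", "P1"), (5, "rep1")] == pytest.approx(0.28)

    def test_flat_channels_give_unit_ratios(self, design):
        iodo_rows = {"aVLcAAAADK": [500] * 6, "aVLcAAAAEK": [800] * 6}
        psmset = build_psmset(design, iodo_rows)
        ratios = compute_ratios(median_normalize_iodo(psmset), design)
        assert np.allclose(ratios.values.to_numpy(dtype=float), 1.0)

    def test_matches_elementwise_quotient(self, design):
        rng = np.random.default_rng(23)
        psmset = random_psmset(design, 15, rng)
        from redoxquant.quantify import IntensityMatrix

        matrix = summed_peptide_matrix(psmset, "iodo")
        ratios = compute_ratios(IntensityMatrix(matrix, "iodo", "raw"), design)
        pairs = {5: ("126", "127"), 30: ("128", "129"), 120: ("130", "131")}
        for tp, (control, treated) in pairs.items():
            expected = (
                matrix[("rep1", treated)] / matrix[("rep1", control)]
            ).to_numpy()
            assert np.allclose(
                ratios.values[(tp, "rep1")].to_numpy(dtype=float), expected
            )


class TestRenormalizeRatios:
    def _ratio_matrix(self, values):
        from redoxquant.quantify import RatioMatrix

        frame = pd.DataFrame(
            {(5, "rep1"): values}, index=[f"e{i}" for i in range(len(values))]
        )
        frame.columns = pd.MultiIndex.from_tuples(
            frame.columns, names=["timepoint", "replicate"]
        )
        return RatioMatrix(frame, "iodoTMT-peptide")

    def test_median_one_slice_unchanged(self):
        result = renormalize_ratios(self._ratio_matrix([0.5, 1.0, 2.0]))
        assert list(result.values[(5, "rep1")]) == pytest.approx([0.5, 1.0, 2.0])

    def test_median_division(self):
        result = renormalize_ratios(self._ratio_matrix([2.0, 4.0, 8.0]))
        assert list(result.values[(5, "rep1")]) == pytest.approx([0.5, 1.0, 2.0])

    def test_slice_medians_one_on_random_data(self, design):
        rng = np.random.default_rng(29)
        psmset = random_psmset(design, 21, rng)
        ratios = compute_ratios(median_normalize_iodo(psmset), design)
        result = renormalize_ratios(ratios)
        for col in result.values.columns:
            assert abs(result.values[col].median() - 1.0) < 1e-12


def test_scale_invariance_of_fold_changes(design):
    """Multiplying every intensity in a replicate by a constant must leave
    every downstream fold change unchanged."""
    rng = np.random.default_rng(31)
    iodo_rows = {f"aVLcDE{_suffix(i)}K": rng.uniform(100, 5000, 6) for i in range(9)}
    base = build_psmset(design, {k: list(v) for k, v in iodo_rows.items()})
    scaled = build_psmset(design, {k: list(v * 37.5) for k, v in iodo_rows.items()})
    r1 = renormalize_ratios(compute_ratios(median_normalize_iodo(base), design))
    r2 = renormalize_ratios(compute_ratios(median_normalize_iodo(scaled), design))
    assert np.allclose(
        r1.values.to_numpy(dtype=float), r2.values.to_numpy(dtype=float)
    )
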