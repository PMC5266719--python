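"""Synthetic PSM datasets with known planted redox and abundance effects.

The generator emulates the statistical structure the analysis assumes: a
6-plex control/treatment design over 5/30/120 min, three independent
biological replicates sharing the true fold changes, repeated PSMs per
peptide, multiplicative log-normal reporter noise, and randomly missing
channels.  Crucially it reproduces the confound the dual-label design
exists to resolve: a treated iodoTMT channel carries the product of the
cysteine-oxidation fold change and the protein-abundance fold change, while
iTRAQ channels carry abundance only.

Planted effects may be addressed by generated entity name (annotated peptide
string / protein accession) or, more conveniently, by generation-order index
(the i-th labeled cysteine peptide, the i-th protein).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Union

import numpy as np

from .design import ChannelDesign, CONTROL
from .peptides import Modification, ModifiedPeptide, N_TERM, IODOTMT, ITRAQ
from .psm import PSMRecord, PSMSet

EffectKey = Union[int, str]
EffectMap = Mapping[EffectKey, Mapping[int, float]]

# residues used for random tryptic-like sequences; the first residue avoids
# letters with their own lowercase marking rule so annotations round-trip
_FIRST_RESIDUES = "ADEFGHILNPQVW"
_BODY_RESIDUES = "ADEFGHILNPQSVWTY"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic experiment.

    Defaults mirror the emulated study: three biological replicates, a
    handful of peptides per protein, roughly half the peptides carrying a
    cysteine, and 29% of cysteine peptides actually iodoTMT-labeled (the
    observed labeling rate of the reverse-labeling chemistry).  Noise is
    multiplicative log-normal per channel; ``noise_sigma`` is its standard
    deviation on the log2 scale.
    """

    n_proteins: int = 40
    peptides_per_protein: tuple[int, int] = (2, 4)
    cys_fraction: float = 0.5
    labeled_fraction: float = 0.29
    psm_multiplicity: tuple[int, int] = (1, 3)
    n_replicates: int = 3
    baseline_scale: float = 1e5
    base_spread: float = 1.0  # log2 sd of per-PSM base abundance
    noise_sigma: float = 0.25
    missing_prob: float = 0.0
    compression: float = 1.0  # 1.0 = no ratio compression
    oxidation_effects: EffectMap = field(default_factory=dict)
    abundance_effects: EffectMap = field(default_factory=dict)
    seed: int = 20170126

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("need at least one protein")
        for prob in (self.cys_fraction, self.labeled_fraction, self.missing_prob):
            if not 0 <= prob <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0 < self.compression <= 1:
            raise ValueError("compression factor must be in (0, 1]")
        for effects in (self.oxidation_effects, self.abundance_effects):
            for per_tp in effects.values():
                if any(fc <= 0 for fc in per_tp.values()):
                    raise ValueError("planted fold changes must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted linear fold changes for every generated entity."""

    oxidation: Mapping[str, Mapping[int, float]]  # annotated peptide -> tp -> FC
    abundance: Mapping[str, Mapping[int, float]]  # accession -> tp -> FC


def generate_psm_dataset(
    config: SimulationConfig, design: ChannelDesign | None = None
) -> tuple[PSMSet, SyntheticTruth]:
    """Generate a reproducible PSM dataset and its ground truth.

    In each replicate, every PSM of a peptide draws an independent base
    abundance; a control channel reads base x noise, a treated channel
    additionally multiplies in the planted fold changes for its timepoint
    (oxidation x abundance for iodoTMT, abundance for iTRAQ).  With
    ``noise_sigma = 0`` every treated/control ratio equals the planted
    product exactly.
    """
    if design is None:
        design = ChannelDesign.default(
            tuple(f"rep{i + 1}" for i in range(config.n_replicates))
        )
    if len(design.replicates) != config.n_replicates:
        design = ChannelDesign(
            design.iodo_map,
            design.itraq_map,
            tuple(f"rep{i + 1}" for i in range(config.n_replicates)),
        )
    rng = np.random.default_rng(config.seed)
    timepoints = design.timepoints

    proteins = [f"SYN{i + 1:04d}" for i in range(config.n_proteins)]
    peptides: list[ModifiedPeptide] = []
    labeled_order: list[str] = []  # annotated strings of labeled cys peptides
    seen: set[str] = set()
    for accession in proteins:
        lo, hi = config.peptides_per_protein
        for _ in range(int(rng.integers(lo, hi + 1))):
            peptide = _random_peptide(rng, accession, config, seen)
            peptides.append(peptide)
            if peptide.is_iodo_labeled:
                from .peptides import render_modified_sequence

                labeled_order.append(render_modified_sequence(peptide))

    oxidation = _resolve_effects(
        config.oxidation_effects, labeled_order, timepoints, "oxidation"
    )
    abundance = _resolve_effects(
        config.abundance_effects, proteins, timepoints, "abundance"
    )
    # truth covers every cysteine peptide (unlabeled ones have no planted effect)
    from .peptides import render_modified_sequence

    truth_ox = {
        render_modified_sequence(p): dict(
            oxidation.get(render_modified_sequence(p), {tp: 1.0 for tp in timepoints})
        )
        for p in peptides
        if p.is_cysteine_containing
    }
    truth_ab = {acc: dict(abundance.get(acc, {tp: 1.0 for tp in timepoints})) for acc in proteins}

    records: list[PSMRecord] = []
    for replicate in design.replicates:
        for peptide in peptides:
            annotated = render_modified_sequence(peptide)
            accession = peptide.accessions[0]
            ab = truth_ab.get(accession, {})
            ox = truth_ox.get(annotated, {})
            lo, hi = config.psm_multiplicity
            for _ in range(int(rng.integers(lo, hi + 1))):
                records.append(
                    _simulate_psm(
                        rng, config, design, peptide, replicate, ox, ab
                    )
                )
    return PSMSet(records=tuple(records), design=design), SyntheticTruth(
        oxidation=truth_ox, abundance=truth_ab
    )


def _random_peptide(
    rng: np.random.Generator,
    accession: str,
    config: SimulationConfig,
    seen: set[str],
) -> ModifiedPeptide:
    while True:
        length = int(rng.integers(8, 17))
        chars = [str(rng.choice(list(_FIRST_RESIDUES)))]
        chars += [str(c) for c in rng.choice(list(_BODY_RESIDUES), size=length - 2)]
        chars.append("K" if rng.random() < 0.5 else "R")
        has_cys = rng.random() < config.cys_fraction
        labeled = has_cys and rng.random() < config.labeled_fraction
        if has_cys:
            pos = int(rng.integers(1, length - 1))  # 0-based, internal
            chars[pos] = "C"
        sequence = "".join(chars)
        if sequence in seen:
            continue
        seen.add(sequence)
        mods = [Modification(N_TERM, ITRAQ)]
        if sequence.endswith("K"):
            mods.append(Modification(length, ITRAQ))
        if labeled:
            mods.append(Modification(sequence.index("C") + 1, IODOTMT))
        return ModifiedPeptide(
            sequence=sequence, modifications=tuple(mods), accessions=(accession,)
        )


def _resolve_effects(
    effects: EffectMap,
    names_in_order: list[str],
    timepoints: tuple[int, ...],
    kind: str,
) -> dict[str, dict[int, float]]:
    resolved: dict[str, dict[int, float]] = {}
    for key, per_tp in effects.items():
        if isinstance(key, int):
            if key >= len(names_in_order):
                raise ValueError(
                    f"{kind} effect index {key} exceeds the {len(names_in_order)} "
                    "generated entities"
                )
            name = names_in_order[key]
        else:
            name = key
        full = {tp: 1.0 for tp in timepoints}
        full.update({int(tp): float(fc) for tp, fc in per_tp.items()})
        resolved[name] = full
    return resolved


def _observed_fc(fc: float, compression: float) -> float:
    if compression == 1.0:
        return fc
    return 1.0 + compression * (fc - 1.0)


def _simulate_psm(
    rng: np.random.Generator,
    config: SimulationConfig,
    design: ChannelDesign,
    peptide: ModifiedPeptide,
    replicate: str,
    oxidation: Mapping[int, float],
    abundance: Mapping[int, float],
) -> PSMRecord:
    sigma = config.noise_sigma
    base_iodo = config.baseline_scale * 2.0 ** (
        rng.normal(0.0, config.base_spread) if config.base_spread > 0 else 0.0
    )
    base_itraq = config.baseline_scale * 2.0 ** (
        rng.normal(0.0, config.base_spread) if config.base_spread > 0 else 0.0
    )

    iodo: dict[str, float] = {}
    if peptide.is_iodo_labeled:
        for label, (cond, tp) in sorted(design.iodo_map.items()):
            fc = 1.0
            if cond != CONTROL:
                fc = _observed_fc(
                    oxidation.get(tp, 1.0) * abundance.get(tp, 1.0),
                    config.compression,
                )
            noise = 2.0 ** rng.normal(0.0, sigma) if sigma > 0 else 1.0
            iodo[label] = base_iodo * fc * noise

    itraq: dict[str, float] = {}
    for label, (cond, tp) in sorted(design.itraq_map.items()):
        fc = 1.0
        if cond != CONTROL:
            fc = _observed_fc(abundance.get(tp, 1.0), config.compression)
        noise = 2.0 ** rng.normal(0.0, sigma) if sigma > 0 else 1.0
        itraq[label] = base_itraq * fc * noise

    if config.missing_prob > 0:
        iodo = {
            label: value
            for label, value in iodo.items()
            if rng.random() >= config.missing_prob
        }
        kept = {
            label: value
            for label, value in itraq.items()
            if rng.random() >= config.missing_prob
        }
        # a PSM is only reported with at least one iTRAQ reporter observed
        itraq = kept if kept else {"113": itraq["113"]}

    return PSMRecord(
        peptide=peptide,
        replicate=replicate,
        iodo_intensities=iodo,
        itraq_intensities=itraq,
    )


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named study scenarios with documented planted effects.

    * ``null``: noise-free, no effects — the exact null.
    * ``null_noisy``: no effects, log2 noise sd 0.2, ~2000 labeled cysteine
      peptides — for false-positive-rate calibration.
    * ``glp_like``: one labeled peptide whose parent protein's abundance drops
      (0.76/0.75/0.95 at 5/30/120 min) with no thiol oxidation — the
      abundance-driven decoy case.
    * ``nr_like``: exactly one peptide oxidized 1.51-fold at 30 min with no
      protein-level change — the pure-redox case.
    * ``mixed``: ten pure-redox peptides (FC 2.0 at 30 min), five
      pure-abundance proteins (FC 0.5 across the course), log2 noise sd 0.1.
    """
    base = SimulationConfig(
        n_proteins=40,
        peptides_per_protein=(2, 4),
        cys_fraction=0.5,
        labeled_fraction=1.0,
        psm_multiplicity=(1, 3),
        noise_sigma=0.1,
    )
    presets = {
        "null": replace(base, noise_sigma=0.0),
        "null_noisy": SimulationConfig(
            n_proteins=500,
            peptides_per_protein=(4, 4),
            cys_fraction=1.0,
            labeled_fraction=1.0,
            psm_multiplicity=(1, 1),
            noise_sigma=0.2,
        ),
        "glp_like": replace(
            base,
            noise_sigma=0.05,
            peptides_per_protein=(3, 5),
            abundance_effects={0: {5: 0.76, 30: 0.75, 120: 0.95}},
        ),
        "nr_like": replace(
            base,
            oxidation_effects={0: {30: 1.51}},
        ),
        "mixed": replace(
            base,
            n_proteins=60,
            oxidation_effects={i: {30: 2.0} for i in range(10)},
            abundance_effects={
                i: {5: 0.5, 30: 0.5, 120: 0.5} for i in range(50, 55)
            },
        ),
    }
    return presets
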