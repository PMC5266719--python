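"""End-to-end orchestration: simulate -> discover -> cluster, with manifests.

Runs are reproducible: an identical configuration and seed produce
byte-identical output files, and every run writes a manifest recording the
configuration hash, the seed, and the artifacts produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .cluster import cluster_sizes, cut_tree, write_cdt_gtr
from .design import ChannelDesign, read_design
from .io import write_psm_table
from .model import RedoxQuantModel
from .simulate import SimulationConfig, SyntheticTruth, generate_psm_dataset, scenario_presets


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``preset`` (synthetic data) or ``psm_path`` (an existing
    PSM table) must be given.
    """

    outdir: str
    preset: Optional[str] = None
    psm_path: Optional[str] = None
    design_path: Optional[str] = None
    alpha: float = 0.05
    min_reps: int = 2
    renormalize_iodo: bool = True
    renormalize_itraq: bool = True
    bh: bool = False
    welch: bool = False
    cluster_which: str = "significant"
    cluster_distance: str = "uncentered"
    cluster_linkage: str = "average"
    cluster_k: int = 2
    seed: int = 20170126

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if (self.preset is None) == (self.psm_path is None):
            raise ValueError("give exactly one of preset or psm_path")

    def as_manifest_dict(self) -> dict:
        """Config fields that determine the outputs (the output location
        itself does not)."""
        doc = dataclasses.asdict(self)
        doc.pop("outdir")
        return doc

    def sha256(self) -> str:
        doc = json.dumps(self.as_manifest_dict(), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()


def write_truth_table(truth: SyntheticTruth, path: str) -> None:
    """Planted fold changes as TSV: entity type, entity, FC per timepoint."""
    tps = sorted({tp for per in truth.oxidation.values() for tp in per} |
                 {tp for per in truth.abundance.values() for tp in per})
    with open(path, "w") as fh:
        fh.write("entity_type\tentity\t" + "\t".join(f"fc_{tp}" for tp in tps) + "\n")
        for name in sorted(truth.oxidation):
            per = truth.oxidation[name]
            fh.write("peptide_oxidation\t" + name + "\t"
                     + "\t".join(repr(per.get(tp, 1.0)) for tp in tps) + "\n")
        for name in sorted(truth.abundance):
            per = truth.abundance[name]
            fh.write("protein_abundance\t" + name + "\t"
                     + "\t".join(repr(per.get(tp, 1.0)) for tp in tps) + "\n")


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest dict.

    Artifacts written to ``config.outdir``: the PSM and truth tables (when
    simulating), the per-peptide results TSV, a JSON summary, cluster files
    (CDT/GTR/Newick plus a TSV of assignments) when at least two significant
    peptides exist, and ``manifest.json``.
    """
    os.makedirs(config.outdir, exist_ok=True)
    outputs: list[str] = []
    notes: dict[str, str] = {}

    def path(name: str) -> str:
        outputs.append(name)
        return os.path.join(config.outdir, name)

    # --- stage: input -----------------------------------------------------
    try:
        if config.preset is not None:
            presets = scenario_presets()
            if config.preset not in presets:
                raise ValueError(
                    f"unknown preset {config.preset!r}; have {sorted(presets)}"
                )
            sim = dataclasses.replace(presets[config.preset], seed=config.seed)
            psmset, truth = generate_psm_dataset(sim)
            write_psm_table(psmset, path("psms.tsv"))
            write_truth_table(truth, path("truth.tsv"))
        else:
            design = (
                read_design(config.design_path)
                if config.design_path
                else ChannelDesign.default()
            )
            from .io import read_psm_table

            psmset = read_psm_table(config.psm_path, design)
    except Exception as exc:
        raise PipelineError(f"stage input: {exc}") from exc

    # --- stage: discover --------------------------------------------------
    try:
        model = RedoxQuantModel(
            psmset,
            renormalize_iodo=config.renormalize_iodo,
            renormalize_itraq=config.renormalize_itraq,
        )
        results = model.fit(
            alpha=config.alpha,
            min_reps=config.min_reps,
            bh=config.bh,
            welch=config.welch,
        )
        results.to_results_table(path("results.tsv"))
        results.write_summary_json(path("summary.json"))
    except Exception as exc:
        raise PipelineError(f"stage discover: {exc}") from exc

    # --- stage: cluster ---------------------------------------------------
    try:
        matrix = results.profile_matrix(config.cluster_which)
        if len(matrix) >= 2:
            tree = results.cluster_tree(
                config.cluster_which,
                distance=config.cluster_distance,
                linkage=config.cluster_linkage,
            )
            k = min(config.cluster_k, len(matrix))
            assignment = cut_tree(tree, k)
            with open(path("clusters.nwk"), "w") as fh:
                fh.write(tree.to_newick() + "\n")
            write_cdt_gtr(tree, matrix, path("clusters.cdt"), path("clusters.gtr"))
            with open(path("cluster_assignments.tsv"), "w") as fh:
                fh.write("entity\tcluster\n")
                for name in tree.leaf_order():
                    fh.write(f"{name}\t{assignment[name]}\n")
            notes["cluster_sizes"] = ",".join(
                str(s) for s in cluster_sizes(assignment)
            )
        else:
            notes["cluster"] = (
                f"skipped: only {len(matrix)} {config.cluster_which} peptides"
            )
    except Exception as exc:
        raise PipelineError(f"stage cluster: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": config.as_manifest_dict(),
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "outputs": sorted(outputs),
        "notes": notes,
        "summary": results.summary_counts(),
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
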