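"""End-to-end pipeline: (simulate →) fit → modes → sets → candidates.

``run_pipeline`` executes the stages in order, writes every stage table
as TSV plus a machine-readable JSON run report, and is fully
deterministic given the seed.  The report is derived from the stage
outputs — every number in it can be recomputed from the written TSVs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import pandas as pd

from .data import (
    AnnotationTable,
    PipelineConfig,
    read_annotations,
    read_counts,
    write_json,
    write_table,
)
from .errors import PipelineError, StressModesError
from .model import StressResponseModel
from .simulate import SimConfig, default_design, build_truth, simulate_counts

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunReport:
    """Derived summary of one pipeline run."""

    config: dict
    stages: dict
    manifest: dict

    def to_dict(self) -> dict:
        return {"config": self.config, "stages": self.stages, "manifest": self.manifest}


def _stage(name, fn, stages, *args, **kwargs):
    # timings go to the log only, so reports are byte-identical across runs
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except StressModesError as exc:
        stages.setdefault(name, {})["status"] = "failed"
        raise PipelineError(name, str(exc)) from exc
    logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
    stages.setdefault(name, {})["status"] = "ok"
    return out


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    counts_path=None,
    design_path=None,
    annotations_path=None,
    sim_config: SimConfig | None = None,
) -> RunReport:
    """Run every stage and write TSV outputs plus ``report.json``.

    Either ``counts_path``/``design_path`` point at real input files, or
    ``sim_config`` requests a synthetic dataset (the truth table is then
    written alongside the counts).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    manifest: dict = {}

    if sim_config is not None:
        sim_config = dataclasses.replace(sim_config, rng_seed=config.rng_seed)

        def simulate():
            truth = build_truth(sim_config)
            design = default_design(sim_config.replicates)
            counts = simulate_counts(truth, design, sim_config)
            return truth, design, counts

        truth, design, counts = _stage("simulate", simulate, stages)
        write_table(truth.reset_index(), out_dir / "truth.tsv")
        write_table(counts.counts.reset_index(names="gene_id"), out_dir / "counts.tsv")
        design_df = pd.DataFrame(
            {"sample_id": list(design.mapping), "condition": list(design.mapping.values())}
        )
        design_df.to_csv(out_dir / "design.tsv", sep="\t", index=False, header=False)
        manifest.update(
            truth=str(out_dir / "truth.tsv"),
            counts=str(out_dir / "counts.tsv"),
            design=str(out_dir / "design.tsv"),
        )
        stages["simulate"]["n_genes"] = len(truth)
        stages["simulate"]["n_samples"] = len(design.mapping)
    else:
        if counts_path is None or design_path is None:
            raise PipelineError("read_counts", "need counts and design paths (or a sim config)")
        counts, design = _stage(
            "read_counts", read_counts, stages, counts_path, design_path,
            aliases=config.condition_aliases,
        )
        stages["read_counts"]["n_genes"] = counts.shape[0]
        stages["read_counts"]["n_samples"] = counts.shape[1]

    annotations = None
    if annotations_path is not None:
        annotations = _stage("read_annotations", read_annotations, stages, annotations_path)

    model = StressResponseModel(counts, design, config=config)
    results = _stage("de", model.fit, stages)
    manifest.update(results.to_files(out_dir))
    stages["de"]["degs"] = {
        name: int(table["significant"].sum()) for name, table in results.contrasts.items()
    }

    assignments = _stage("modes", results.profile_assignments, stages)
    write_table(assignments.reset_index(), out_dir / "modes.tsv")
    manifest["modes"] = str(out_dir / "modes.tsv")
    summary = results.mode_summary(top_n=max(config.top_n_list))
    stability = _stage("stability", results.stability, stages, config.top_n_list)
    write_table(stability.to_frame(), out_dir / "mode_stability.tsv")
    manifest["mode_stability"] = str(out_dir / "mode_stability.tsv")
    stages["modes"]["fractions"] = summary.fractions
    stages["modes"]["unpredictable_fraction"] = summary.unpredictable_fraction
    stages["stability"]["max_deviation"] = stability.max_deviation

    def sets_stage():
        venn_all = results.venn()
        venn_up = results.venn("up")
        venn_down = results.venn("down")
        from .sets import overlap_statistics

        stats = overlap_statistics(venn_all, up=venn_up, down=venn_down)
        frames = []
        for label, dec in (("all", venn_all), ("up", venn_up), ("down", venn_down)):
            frame = dec.to_frame()
            frame.insert(0, "direction", label)
            frames.append(frame)
        venn_table = pd.concat(frames, ignore_index=True)
        contributions = {
            s: results.contribution(s, n=config.contribution_n) for s in ("CT", "DT")
        }
        return venn_table, stats, contributions

    venn_table, overlap, contributions = _stage("sets", sets_stage, stages)
    write_table(venn_table, out_dir / "venn.tsv")
    manifest["venn"] = str(out_dir / "venn.tsv")
    stages["sets"]["overlap"] = overlap
    stages["sets"]["contribution"] = {
        s: {"absolute": c.absolute, "signed": c.signed} for s, c in contributions.items()
    }

    def candidates_stage():
        return results.candidates(
            margin=config.enhancement_margin, k=config.subgroup_k, annotations=annotations
        )

    cset = _stage("candidates", candidates_stage, stages)
    write_table(cset.table.reset_index(), out_dir / "candidates.tsv")
    manifest["candidates"] = str(out_dir / "candidates.tsv")
    stages["candidates"]["n_co_up"] = len(cset.co_up_genes)
    stages["candidates"]["n_retained"] = len(cset.retained_genes)

    report = RunReport(
        config={
            **dataclasses.asdict(config),
            "top_n_list": list(config.top_n_list),
            "simulated": sim_config is not None,
            **({"sim": dataclasses.asdict(sim_config)} if sim_config is not None else {}),
        },
        stages=stages,
        manifest=manifest,
    )
    write_json(report.to_dict(), out_dir / "report.json")
    return report
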