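"""End-to-end orchestration: simulate/load -> rhythm screen -> rhythm
comparison -> differential screens -> enrichment, with a run manifest.

Outputs are a pure function of (inputs, config, seed): every stochastic
stage draws from a stream derived from the master seed with a fixed label,
so enabling or disabling one stage never changes another stage's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataio import AnalysisConfig, MetaboliteTable, read_metabolite_table, \
    validate_design, write_metabolite_table
from .enrichment import PathwayMap, enrich
from .jtk import reduction_pct, screen_rhythmic
from .rhythms import compare_rhythms, nocturnal_fraction
from .screening import fold_change_screen, shared_by_exactly, timepoint_screen, \
    timepoint_union, venn_counts
from .synthetic import GeneratorConfig, generate_dataset, synthetic_pathway_map

logger = logging.getLogger("chronometab")

STAGE_SEED_LABELS = {"simulate": 11, "screen": 23, "compare": 31,
                     "diff": 47, "enrich": 59}


def _stage_seed(master: int, stage: str) -> int:
    return int(np.random.SeedSequence((master, STAGE_SEED_LABELS[stage]))
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class RunManifest:
    seed: int
    config: dict
    generator: dict | None
    inputs: dict[str, str]          # path -> sha256
    outputs: dict[str, str]         # stage -> path
    counts: dict[str, float] = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    version: str = __version__

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: AnalysisConfig, outdir: str | Path, *,
                 table: MetaboliteTable | None = None,
                 table_path: str | Path | None = None,
                 meta_path: str | Path | None = None,
                 generator_config: GeneratorConfig | None = None,
                 pathway_map: PathwayMap | None = None) -> RunManifest:
    """Run every applicable stage, writing one CSV per stage plus a manifest.

    Exactly one input source must be given: an in-memory table, a CSV pair,
    or a generator configuration (simulation mode, which also writes ground
    truth and uses a synthetic pathway map unless one is supplied).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=config.to_dict(),
                           generator=None, inputs={}, outputs={})
    gt = None

    if generator_config is not None:
        generator_config = dataclasses.replace(
            generator_config, seed=_stage_seed(config.seed, "simulate"))
        table, gt = generate_dataset(generator_config)
        manifest.generator = dataclasses.asdict(generator_config)
        write_metabolite_table(table, outdir / "abundance.csv", outdir / "metadata.csv")
        gt.table.to_csv(outdir / "ground_truth.csv")
        manifest.outputs["simulate"] = str(outdir / "abundance.csv")
        manifest.stages_completed.append("simulate")
        logger.info("simulated %d metabolites x %d samples",
                    len(table.metabolite_ids), len(table.sample_ids))
    elif table is None:
        if table_path is None or meta_path is None:
            raise ValueError("supply a table, a CSV pair, or a generator config")
        table = read_metabolite_table(table_path, meta_path)
        manifest.inputs[str(table_path)] = _sha256(Path(table_path))
        manifest.inputs[str(meta_path)] = _sha256(Path(meta_path))

    design = validate_design(table, config)
    for note in design.warnings:
        logger.warning(note)

    # rhythm screen -----------------------------------------------------
    screens = {}
    for group in design.groups:
        screens[group] = screen_rhythmic(table, group, config)
        screens[group].results.to_csv(outdir / f"rhythm_{group}.csv")
        manifest.outputs[f"rhythm_{group}"] = str(outdir / f"rhythm_{group}.csv")
        manifest.counts[f"rhythmic_{group}"] = screens[group].n_rhythmic
        logger.info("rhythmic in %s: %d", group, screens[group].n_rhythmic)
    manifest.stages_completed.append("screen-rhythm")
    if len(design.groups) == 2:
        n_ld = screens["LD"].n_rhythmic
        n_ll = screens["LL"].n_rhythmic
        if n_ld > 0:
            red = reduction_pct(n_ld, n_ll)
            manifest.counts["reduction_pct"] = round(red, 1)
            logger.info("rhythmic reduction LD->LL: %d -> %d (%.1f%%)",
                        n_ld, n_ll, red)

    if not design.comparison_enabled:
        logger.info("single-group design: comparison and differential "
                    "screens skipped")
        manifest.write(outdir / "manifest.json")
        return manifest

    # rhythm comparison --------------------------------------------------
    rhythmic_ids = screens["LD"].rhythmic_ids
    disruption = compare_rhythms(table, rhythmic_ids, config)
    disruption.to_csv(outdir / "disruption.csv")
    manifest.outputs["compare-rhythm"] = str(outdir / "disruption.csv")
    manifest.counts["disrupted"] = int(disruption["disrupted"].sum())
    manifest.counts["nocturnal_pct_LD"] = round(
        100 * nocturnal_fraction(disruption["acrophase_ld"], config.period), 1)
    ll_common = [m for m in screens["LL"].rhythmic_ids if m in disruption.index]
    if ll_common:
        manifest.counts["nocturnal_pct_LL"] = round(
            100 * nocturnal_fraction(disruption.loc[ll_common, "acrophase_ll"],
                                     config.period), 1)
    manifest.stages_completed.append("compare-rhythm")
    logger.info("disrupted (interaction p < %.3g): %d of %d rhythmic",
                config.p_threshold, manifest.counts["disrupted"], len(rhythmic_ids))

    # differential screens ------------------------------------------------
    global_screen = fold_change_screen(table, config)
    global_screen.to_csv(outdir / "global_screen.csv")
    manifest.outputs["diff-global"] = str(outdir / "global_screen.csv")
    manifest.counts["global_hits"] = int(global_screen["passes_global"].sum())
    logger.info("global differential hits (FC & p): %d",
                manifest.counts["global_hits"])

    zt_screens = {}
    for zt in table.timepoints:
        zt_screens[float(zt)] = timepoint_screen(table, float(zt), config)
    frames = [df for df in zt_screens.values() if df is not None]
    if frames:
        tp = pd.concat(frames)
        tp.to_csv(outdir / "timepoint_screen.csv")
        manifest.outputs["diff-timepoint"] = str(outdir / "timepoint_screen.csv")
        for zt, df in zt_screens.items():
            if df is not None:
                manifest.counts[f"zt{zt:g}_hits"] = int(df["passes_timepoint"].sum())
        union = timepoint_union(zt_screens)
        manifest.counts["timepoint_union_hits"] = len(union)
        logger.info("timepoint-specific hits (union over ZTs): %d", len(union))
        hit_sets = [set(df.index[df["passes_timepoint"]])
                    for df in zt_screens.values() if df is not None]
        if len(hit_sets) >= 2:
            counts = venn_counts(hit_sets)
            venn_df = pd.DataFrame(
                [{"membership": "".join(map(str, key)), "count": c}
                 for key, c in sorted(counts.items())])
            venn_df.to_csv(outdir / "venn_counts.csv", index=False)
            manifest.outputs["venn"] = str(outdir / "venn_counts.csv")
            manifest.counts["shared_all_timepoints"] = shared_by_exactly(
                counts, len(hit_sets))
    manifest.stages_completed.append("diff")

    # enrichment -----------------------------------------------------------
    if pathway_map is None and gt is not None:
        pathway_map = synthetic_pathway_map(gt, seed=_stage_seed(config.seed, "enrich"))
    if pathway_map is not None:
        hits = [m for m in disruption.index[disruption["disrupted"]]
                if m in pathway_map.background]
        if hits:
            enr = enrich(hits, pathway_map, config)
            enr.to_csv(outdir / "enrichment.csv", index=False)
            manifest.outputs["enrich"] = str(outdir / "enrichment.csv")
            manifest.counts["enriched_pathways"] = int(enr["significant"].sum())
            logger.info("enriched pathways at FDR < %.3g: %d",
                        config.fdr_threshold, manifest.counts["enriched_pathways"])
        else:
            logger.info("no disrupted metabolites map to the background; "
                        "enrichment skipped")
        manifest.stages_completed.append("enrich")
    else:
        logger.info("no pathway map available; enrichment skipped")

    manifest.write(outdir / "manifest.json")
    return manifest
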