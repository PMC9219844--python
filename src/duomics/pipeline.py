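"""End-to-end orchestration: configuration, staged execution, run report.

The pipeline ties the stages together over a fixture directory (either
simulated or assembled from real exports in the same formats):

    align -> average replicates -> feature tests -> annotate
          -> gene DE -> per-layer EC sets -> overlap -> reactions
          -> pathway enrichment -> exports

All randomness flows from one seed; two runs with the same configuration
produce byte-identical tabular outputs.  Any stage failure aborts the run
with the stage name and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_table
from .chem import load_adducts, load_compounds
from .enrich import pathway_activity, results_to_frame
from .integrate import (
    MappingTables,
    ecs_from_degs,
    ecs_from_metabolites,
    export_ipath,
    overlap_ecs,
    reactions_for_ecs,
)
from .metabolomics import (
    FeatureTable,
    align_retention,
    average_technical_replicates,
    differential_analysis,
)
from .rnaseq import de_test

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline"]

logger = logging.getLogger("duomics")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline knobs; thresholds are probabilities in (0, 1).

    ``q_meta`` is the default metabolite significance tier (BH-FDR),
    ``p_meta_strict`` the stricter raw-p tier used for the metabolite->EC
    step and enrichment, ``q_rna`` the transcript tier.
    """

    fixture_dir: str = "."
    out_dir: str = "out"
    tol_ppm: float = 10.0
    q_meta: float = 0.05
    p_meta_strict: float = 0.001
    q_rna: float = 0.05
    co_elution_window: float = 0.2
    anchor_min_presence: float = 1.0
    pseudo: float = 1.0
    tier: str = "gold"
    n_permutations: int = 999
    seed: int = 0

    def validate(self) -> None:
        for name in ("q_meta", "p_meta_strict", "q_rna"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """Per-stage record counts plus the configuration echo."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    n_features_tested: int = 0
    n_features_significant_q: int = 0
    n_features_significant_strict: int = 0
    n_features_annotated: int = 0
    n_adduct_groups: int = 0
    n_genes_tested: int = 0
    n_degs: int = 0
    n_transcript_ecs: int = 0
    n_metabolite_ecs: int = 0
    n_overlap_ecs: int = 0
    n_reactions: int = 0
    n_reactions_overlap: int = 0
    n_pathways_scored: int = 0

    def check(self) -> None:
        counts = {k: v for k, v in dataclasses.asdict(self).items() if isinstance(v, int)}
        if any(v < 0 for v in counts.values()):
            raise ValueError("negative count in run report")
        if self.n_features_significant_q > self.n_features_tested:
            raise ValueError("significant features exceed tested features")
        if self.n_degs > self.n_genes_tested:
            raise ValueError("DEGs exceed tested genes")
        if self.n_overlap_ecs > min(self.n_transcript_ecs, self.n_metabolite_ecs):
            raise ValueError("overlap exceeds a layer EC set")
        if self.n_reactions_overlap > self.n_reactions:
            raise ValueError("overlap reactions exceed total reactions")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _read_runs(fixture: Path) -> tuple[list, dict, str, Optional[dict]]:
    sheet = pd.read_csv(fixture / "samples_metabolomics.tsv", sep="\t", comment="#")
    groups = dict(zip(sheet["sample"], sheet["group"]))
    fraction = sheet["fraction"].iloc[0] if "fraction" in sheet.columns else "pellet"
    tech_map = (
        dict(zip(sheet["sample"], sheet["bio_sample"])) if "bio_sample" in sheet.columns else None
    )
    runs = []
    for sample in sheet["sample"]:
        path = fixture / "runs" / f"{sample}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing run table {path}")
        runs.append((sample, pd.read_csv(path, sep="\t")))
    return runs, groups, fraction, tech_map


def _write_table(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# duomics {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages over ``config.fixture_dir`` into ``config.out_dir``."""
    config.validate()
    fixture = Path(config.fixture_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report = RunReport(config=dataclasses.asdict(config))

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        _write_table(df, path, config.seed)
        written.append(path)

    stage = "load"
    try:
        registry = load_compounds(fixture / "compounds.tsv")
        adducts = load_adducts(fixture / "adducts.tsv")
        maps = MappingTables.from_dir(fixture)
        runs, groups, fraction, tech_map = _read_runs(fixture)

        stage = "align"
        logger.info("align: %d runs", len(runs))
        table = align_retention(
            runs,
            mz_tol_ppm=config.tol_ppm,
            anchor_min_presence=config.anchor_min_presence,
            sample_groups=groups,
            fraction=fraction,
        )

        stage = "average_replicates"
        if tech_map:
            table = average_technical_replicates(table, tech_map)

        stage = "metabolomics_diff"
        diff = differential_analysis(table, pseudo=config.pseudo)
        report.n_features_tested = len(diff)
        report.n_features_significant_q = int((diff["q_value"] < config.q_meta).sum())
        report.n_features_significant_strict = int(
            (diff["p_value"] < config.p_meta_strict).sum()
        )
        emit(diff, "differential_metabolites.tsv")
        logger.info(
            "metabolomics: %d features, %d at q<%g",
            report.n_features_tested,
            report.n_features_significant_q,
            config.q_meta,
        )

        stage = "annotate"
        annotated, groups_list = annotate_table(
            diff, registry, adducts, tol_ppm=config.tol_ppm,
            co_elution_window=config.co_elution_window,
        )
        report.n_features_annotated = int((annotated["compound"] != "unannotated").sum())
        report.n_adduct_groups = len(groups_list)
        emit(annotated, "annotated_metabolites.tsv")
        emit(
            pd.DataFrame(
                {
                    "group_id": [g.group_id for g in groups_list],
                    "compound": [g.compound for g in groups_list],
                    "n_features": [len(g.feature_ids) for g in groups_list],
                    "rt_spread": [g.rt_spread for g in groups_list],
                    "feature_ids": [";".join(g.feature_ids) for g in groups_list],
                }
            ),
            "adduct_groups.tsv",
        )

        stage = "rnaseq_diff"
        counts = pd.read_csv(fixture / "counts.tsv", sep="\t", index_col="gene")
        rna_sheet = pd.read_csv(fixture / "samples_rnaseq.tsv", sep="\t", comment="#")
        rna_groups = dict(zip(rna_sheet["sample"], rna_sheet["group"]))
        degs = de_test(counts, rna_groups, pseudo=config.pseudo)
        report.n_genes_tested = len(degs)
        report.n_degs = int((degs["q_value"] < config.q_rna).sum())
        emit(degs, "differential_genes.tsv")
        logger.info("rnaseq: %d genes, %d DEGs", report.n_genes_tested, report.n_degs)

        stage = "ec_integration"
        transcript_ecs = ecs_from_degs(degs, maps, q_threshold=config.q_rna, tier=config.tier)
        metabolite_ecs = ecs_from_metabolites(
            annotated, maps, registry=registry, p_threshold=config.p_meta_strict
        )
        overlap = overlap_ecs(transcript_ecs, metabolite_ecs)
        report.n_transcript_ecs = len(transcript_ecs)
        report.n_metabolite_ecs = len(metabolite_ecs)
        report.n_overlap_ecs = len(overlap)
        for name, ecs in (
            ("ec_transcript.txt", transcript_ecs),
            ("ec_metabolite.txt", metabolite_ecs),
            ("ec_overlap.txt", overlap),
        ):
            path = out_dir / name
            path.write_text(
                "\n".join(sorted(ecs)) + ("\n" if ecs else ""), encoding="utf-8"
            )
            written.append(path)
        logger.info(
            "integration: %d transcript ECs, %d metabolite ECs, %d overlap",
            len(transcript_ecs), len(metabolite_ecs), len(overlap),
        )

        stage = "reactions"
        records = reactions_for_ecs(
            transcript_ecs | metabolite_ecs, maps, (transcript_ecs, metabolite_ecs)
        )
        overlap_reactions = {
            rxn for ec in overlap for rxn in maps.ec_reaction.get(ec, ())
        }
        report.n_reactions = len(records)
        report.n_reactions_overlap = len(overlap_reactions)
        emit(
            pd.DataFrame(
                {
                    "reaction": [r.reaction for r in records],
                    "evidence": [r.evidence for r in records],
                    "ecs": [";".join(sorted(r.ecs)) for r in records],
                    "pathways": [";".join(sorted(r.pathways)) for r in records],
                }
            ),
            "reactions.tsv",
        )
        if records:
            ipath_path = out_dir / "ipath_selection.txt"
            export_ipath(records, ipath_path)
            written.append(ipath_path)

        stage = "enrichment"
        pw = pd.read_csv(fixture / "pathway_compounds.tsv", sep="\t", comment="#")
        pathway_compounds: dict = {}
        for _, row in pw.iterrows():
            pathway_compounds.setdefault(row["pathway"], set()).add(row["compound"])
        results = pathway_activity(
            annotated,
            pathway_compounds,
            sig_threshold=config.p_meta_strict,
            B=config.n_permutations,
            seed=config.seed,
        )
        report.n_pathways_scored = len(results)
        emit(results_to_frame(results), "pathway_enrichment.tsv")

        stage = "report"
        report.check()
        report_path = out_dir / "run_report.json"
        report_path.write_text(report.to_json(), encoding="utf-8")
        written.append(report_path)
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise PipelineError(stage, exc) from exc
    return report
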