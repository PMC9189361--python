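"""End-to-end orchestration of the synthetic study.

One call generates the promoter, simulates bisulfite reads and calls the
methylation rate, simulates the stage cohort and runs the association
layer, scores tumor-mask regularity and section invasion, and writes every
table plus a machine-readable summary stating whether the qualitative
expectations (island count, stage ordering, slope signs) hold.

Stage outputs are flat TSV/JSON files; a manifest of config checksums lets
unchanged stages be skipped on rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import association, invasion, io, methylation, morphometry, synthetic

logger = logging.getLogger("methmorph")

__all__ = ["RunConfig", "PipelineStageError", "run_end_to_end"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run.

    Sub-stage seeds are derived from ``seed`` by fixed offsets so every
    stage is independently reproducible.
    """

    outdir: str = "methmorph_run"
    seed: int = 0
    log_level: str = "INFO"
    promoter: dict = field(default_factory=lambda: {"length": 2000, "n_islands": 3})
    reads: dict = field(
        default_factory=lambda: {
            "depth": 200,
            "p_meth": 0.7,
            "amplicon_margin": 40,
            "seq_error_rate": 0.0,
            "conversion_rate": 1.0,
        }
    )
    cohort: dict = field(default_factory=lambda: {"noise_scale": 1.0})
    masks: dict = field(
        default_factory=lambda: {
            "n_per_group": 8,
            "regular_radius": 40,
            "irregular_perturbation": 0.25,
            "size_px": 160,
        }
    )
    sections: list = field(default_factory=lambda: [[120, 30, 100], [120, 60, 100], [120, 90, 100]])

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _stage_hash(name: str, payload: Any) -> str:
    blob = json.dumps([name, payload], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict[str, dict] = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def fresh(self, stage: str, digest: str, outputs: list[Path]) -> bool:
        entry = self.data.get(stage)
        return bool(entry and entry["hash"] == digest and all(Path(p).exists() for p in entry["outputs"]))

    def record(self, stage: str, digest: str, outputs: list[Path]) -> None:
        self.data[stage] = {"hash": digest, "outputs": [str(p) for p in outputs]}
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_end_to_end(config: RunConfig | None = None) -> dict[str, Any]:
    """Run every stage; returns the summary dictionary (also written to
    ``summary.json`` in the output directory)."""
    config = config or RunConfig()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    manifest = _Manifest(out / "manifest.json")
    summary: dict[str, Any] = {"seed": config.seed}

    # --- stage: promoter -------------------------------------------------
    stage = "promoter"
    fasta, bed = out / "promoter.fasta", out / "islands.bed"
    digest = _stage_hash(stage, [config.promoter, config.seed])
    try:
        if manifest.fresh(stage, digest, [fasta, bed]):
            logger.info("stage %s: up to date, skipping", stage)
            region = io.read_region_fasta(fasta)
        else:
            logger.info("stage %s: generating promoter", stage)
            spec = synthetic.PromoterSpec(seed=config.seed + 11, **config.promoter)
            region = synthetic.generate_promoter(spec)
            io.write_fasta(region, fasta)
            io.write_islands_bed(region, bed)
            manifest.record(stage, digest, [fasta, bed])
        summary["n_islands_detected"] = len(region.islands)
        summary["n_cpg_sites"] = len(region.cpg_sites)
        summary["islands_as_expected"] = len(region.islands) == config.promoter.get("n_islands", 3)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # --- stage: reads + methylation call ---------------------------------
    stage = "methylation"
    fastq = out / "reads.fastq"
    site_tsv = out / "methylation_sites.tsv"
    region_tsv = out / "methylation_region.tsv"
    digest = _stage_hash(stage, [config.reads, config.seed])
    try:
        if manifest.fresh(stage, digest, [fastq, site_tsv, region_tsv]):
            logger.info("stage %s: up to date, skipping", stage)
            r_m = float(pd.read_csv(region_tsv, sep="\t")["r_m"][0])
        else:
            logger.info("stage %s: simulating %d reads and calling", stage, config.reads["depth"])
            margin = config.reads.get("amplicon_margin", 40)
            if region.islands:
                a, b = region.islands[0]
                amplicon = region.subregion(max(0, a - margin), min(len(region), b + margin), name="amplicon")
            else:
                amplicon = region.subregion(0, min(len(region), 400), name="amplicon")
            profile = synthetic.uniform_profile(amplicon, config.reads["p_meth"])
            params = synthetic.ReadSimParams(
                depth=config.reads["depth"],
                seq_error_rate=config.reads.get("seq_error_rate", 0.0),
                conversion_rate=config.reads.get("conversion_rate", 1.0),
                seed=config.seed + 23,
            )
            reads = synthetic.simulate_bisulfite_reads(amplicon, profile, params)
            io.write_fastq(reads, fastq)
            table = methylation.call_sample(amplicon, [(rid, seq) for rid, seq, _ in reads])
            io.write_site_table(table, amplicon, site_tsv)
            pd.DataFrame(
                [{"sample_id": "synthetic_sample", "region": amplicon.name, "r_m": table.region_rate()}]
            ).to_csv(region_tsv, sep="\t", index=False)
            manifest.record(stage, digest, [fastq, site_tsv, region_tsv])
            # summaries always come from the written file so that fresh and
            # resumed runs report bitwise-identical numbers
            r_m = float(pd.read_csv(region_tsv, sep="\t")["r_m"][0])
        summary["region_methylation_rate"] = r_m
        summary["methylation_rate_target"] = config.reads["p_meth"]
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # --- stage: cohort + associations ------------------------------------
    stage = "association"
    cohort_tsv = out / "cohort.tsv"
    report_tsv = out / "stage_associations.tsv"
    report_json = out / "stage_associations.json"
    digest = _stage_hash(stage, [config.cohort, config.seed])
    try:
        if manifest.fresh(stage, digest, [cohort_tsv, report_tsv, report_json]):
            logger.info("stage %s: up to date, skipping", stage)
            cohort = io.read_cohort_tsv(cohort_tsv)
            report = pd.read_csv(report_tsv, sep="\t")
        else:
            logger.info("stage %s: simulating cohort and fitting associations", stage)
            params = synthetic.default_cohort_params(
                seed=config.seed + 37,
                noise_scale=config.cohort.get("noise_scale", 1.0),
                null_links=config.cohort.get("null_links", False),
            )
            cohort = synthetic.simulate_cohort(params)
            io.write_cohort_tsv(cohort, cohort_tsv)
            report = association.stage_association_report(cohort)
            report.to_csv(report_tsv, sep="\t", index=False)
            report_json.write_text(report.to_json(orient="records", indent=2))
            manifest.record(stage, digest, [cohort_tsv, report_tsv, report_json])
            cohort = io.read_cohort_tsv(cohort_tsv)
            report = pd.read_csv(report_tsv, sep="\t")
        mm = cohort[cohort["group"].isin(synthetic.MM_GROUPS)]
        meth_means = mm.groupby("group")["meth_rate"].mean()
        upa_means = mm.groupby("group")["upa"].mean()
        mir_means = mm.groupby("group")["mir23"].mean()
        n_signif = int((report["p_slope"] < 0.05).sum())
        # the "any association" statement is Bonferroni-corrected over the
        # panel of slope tests, the same family rule as compare_groups
        alpha_adj = 0.05 / len(report)
        summary["association"] = {
            "all_slope_signs_as_expected": bool(report["sign_ok"].all()),
            "n_significant_slopes": n_signif,
            "any_association_significant": bool((report["p_slope"] < alpha_adj).any()),
            "meth_ordering_ok": bool(
                meth_means.idxmin() == "Intraosseous" and meth_means.idxmax() == "ExtraosseousTumor"
            ),
            "upa_ordering_ok": bool(upa_means.idxmin() == "Intraosseous" and upa_means.idxmax() == "ExtraosseousTumor"),
            "mir23_ordering_ok": bool(
                mir_means.idxmax() == "Intraosseous" and mir_means.idxmin() == "ExtraosseousTumor"
            ),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # --- stage: morphometry ----------------------------------------------
    stage = "morphometry"
    shape_tsv = out / "shape_regularity.tsv"
    digest = _stage_hash(stage, [config.masks, config.seed])
    try:
        if manifest.fresh(stage, digest, [shape_tsv]):
            logger.info("stage %s: up to date, skipping", stage)
            per_tumor = pd.read_csv(shape_tsv, sep="\t", index_col=0)
        else:
            logger.info("stage %s: scoring synthetic tumor masks", stage)
            n = config.masks["n_per_group"]
            size = config.masks["size_px"]
            regular = [
                synthetic.generate_tumor_mask(
                    "circle", size, {"radius": config.masks["regular_radius"] + (k % 5)}, seed=config.seed + k
                )
                for k in range(n)
            ]
            irregular = [
                synthetic.generate_tumor_mask(
                    "perturbed_blob",
                    size,
                    {"radius": config.masks["regular_radius"], "perturbation": config.masks["irregular_perturbation"]},
                    seed=config.seed + 100 + k,
                )
                for k in range(n)
            ]
            per_tumor, _ = morphometry.regularity_report({"regular": regular, "irregular": irregular})
            per_tumor.to_csv(shape_tsv, sep="\t")
            manifest.record(stage, digest, [shape_tsv])
            per_tumor = pd.read_csv(shape_tsv, sep="\t", index_col=0)
        comp = association.compare_groups(
            {g: per_tumor[g].dropna().to_numpy() for g in per_tumor.columns}
        )
        summary["morphometry"] = {
            "mean_f": {g: float(per_tumor[g].mean()) for g in per_tumor.columns},
            "irregular_greater": bool(per_tumor["irregular"].mean() > per_tumor["regular"].mean()),
            "difference_significant": bool(comp.pairwise["significant"].any()),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # --- stage: invasion --------------------------------------------------
    stage = "invasion"
    inv_tsv = out / "invasion.tsv"
    digest = _stage_hash(stage, [config.sections, config.seed])
    try:
        if manifest.fresh(stage, digest, [inv_tsv]):
            logger.info("stage %s: up to date, skipping", stage)
            inv_df = pd.read_csv(inv_tsv, sep="\t")
        else:
            logger.info("stage %s: scoring synthetic sections", stage)
            rows = []
            for i, (total, lesion, width) in enumerate(config.sections, start=1):
                section = synthetic.generate_section(total, lesion, width, seed=config.seed + 200 + i)
                res = invasion.relative_invasion(section)
                rows.append(
                    {
                        "section_id": f"section_{i}",
                        "total_depth_px": res.total_depth,
                        "invaded_depth_px": res.invaded_depth,
                        "relative_invasion": res.relative_invasion,
                    }
                )
            inv_df = pd.DataFrame(rows)
            inv_df.to_csv(inv_tsv, sep="\t", index=False)
            manifest.record(stage, digest, [inv_tsv])
        summary["invasion"] = {
            "relative_invasion": inv_df["relative_invasion"].tolist(),
            "monotone_in_depth": bool(inv_df["relative_invasion"].is_monotonic_increasing),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("run complete: %s", out / "summary.json")
    return summary
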