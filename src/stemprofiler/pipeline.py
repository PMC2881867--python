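"""End-to-end orchestration: simulate -> score -> discriminate ->
diffexpr -> pca -> trend -> heterogeneity, from one YAML-able config.

Every stage writes its tables to the output directory and contributes a
summary block to a machine-readable run report (JSON). Identical
config + seed produces an identical report apart from the timestamp.
A stage failure aborts the run with the stage name, leaving partial
outputs plus a ``FAILED`` marker file in place.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diffexpr as de
from . import heterogeneity as het
from . import profile_structure as ps
from . import stemness
from .expr_io import (
    write_annotation_csv,
    write_expression_tsv,
    write_gmt,
)
from .synthetic_data import SyntheticConfig, generate_cohort, generate_paired_cohort

log = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "score",
    "discriminate",
    "diffexpr",
    "pca",
    "trend",
    "heterogeneity",
)

# prerequisite stages pulled in automatically when a later stage is requested
_DEPS = {
    "simulate": (),
    "score": ("simulate",),
    "discriminate": ("score",),
    "diffexpr": ("simulate",),
    "pca": ("diffexpr",),
    "trend": ("score",),
    "heterogeneity": ("score",),
}


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-serializable)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: tuple[str, ...] = ALL_STAGES
    transform: str = "log2"
    fc_threshold: float = 1.3
    p_threshold: float = 0.05
    n_groups: int = 5
    n_treatment_reference: int = 6
    seed: int = 0

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown} (valid: {list(ALL_STAGES)})")
        if self.transform not in ("linear", "log2"):
            raise ValueError(f"transform must be 'linear' or 'log2', got {self.transform!r}")
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.n_treatment_reference < 1:
            raise ValueError("n_treatment_reference must be >= 1")
        self.synthetic.validate()


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, naming any offending field."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    syn_raw = raw.pop("synthetic", {})
    valid_syn = {f.name for f in dataclasses.fields(SyntheticConfig)}
    bad = set(syn_raw) - valid_syn
    if bad:
        raise ValueError(f"{path}: unknown synthetic fields: {sorted(bad)}")
    valid_run = {f.name for f in dataclasses.fields(RunConfig)} - {"synthetic"}
    bad = set(raw) - valid_run
    if bad:
        raise ValueError(f"{path}: unknown config fields: {sorted(bad)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    cfg = RunConfig(synthetic=SyntheticConfig(**syn_raw), **raw)
    cfg.validate()
    return cfg


def _resolve_stages(requested) -> list[str]:
    needed: set[str] = set()

    def add(stage: str) -> None:
        if stage in needed:
            return
        for dep in _DEPS[stage]:
            add(dep)
        needed.add(stage)

    for s in requested:
        add(s)
    return [s for s in ALL_STAGES if s in needed]


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["stages"] = list(config.stages)
    return d


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the requested stages (plus prerequisites) and return the
    run report, also written to ``<out_dir>/run_report.json``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _resolve_stages(config.stages)
    report: dict = {
        "versions": {
            "stemprofiler": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": _config_dict(config),
        "stages_executed": stages,
        "stage_summaries": {},
        "warnings": [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    state: dict = {}
    current = "setup"
    try:
        for current in stages:
            summary = _STAGE_FUNCS[current](config, state, out)
            report["stage_summaries"][current] = summary
    except Exception as err:
        (out / "FAILED").write_text(f"stage {current}: {err}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_simulate(config: RunConfig, state: dict, out: Path) -> dict:
    syn = dataclasses.replace(config.synthetic, seed=config.seed)
    matrix, annot, truth = generate_cohort(syn)
    paired_syn = dataclasses.replace(
        syn,
        n_samples=12 if syn.n_samples >= 12 else (syn.n_samples // 2) * 2,
        seed=config.seed + 1,
    )
    pmatrix, pannot, ptruth = generate_paired_cohort(paired_syn)

    write_expression_tsv(matrix, out / "cohort_matrix.tsv")
    write_annotation_csv(annot, out / "cohort_annotation.csv")
    (out / "cohort_truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    write_expression_tsv(pmatrix, out / "paired_matrix.tsv")
    write_annotation_csv(pannot, out / "paired_annotation.csv")
    (out / "paired_truth.json").write_text(json.dumps(ptruth.to_dict(), indent=2))
    write_gmt([truth.subset_gene_set(config.synthetic.subset_name)], out / "gene_sets.gmt")

    state.update(
        matrix=matrix, annotation=annot, truth=truth,
        paired_matrix=pmatrix, paired_annotation=pannot, paired_truth=ptruth,
    )
    return {
        "cohort_shape": list(matrix.shape),
        "paired_shape": list(pmatrix.shape),
        "n_reference": len(truth.reference_ids),
        "seed": config.seed,
    }


def _stage_score(config: RunConfig, state: dict, out: Path) -> dict:
    profile = stemness.build_reference_profile(
        state["matrix"], state["truth"].reference_ids
    )
    scores = stemness.score_samples(
        state["matrix"], profile, transform=config.transform
    )
    scores.to_csv(out / "scores.csv", index=False)
    state["scores"] = scores
    return {
        "transform": config.transform,
        "n_samples": len(scores),
        "score_min": float(scores["r"].min()),
        "score_median": float(scores["r"].median()),
        "score_max": float(scores["r"].max()),
    }


def _stage_discriminate(config: RunConfig, state: dict, out: Path) -> dict:
    annot = state["annotation"]
    labels = pd.Series(
        np.where(annot.table["group_label"] == "reference_GSC", "stem_line", "bulk"),
        index=annot.table["sample_id"].tolist(),
    )
    rng = np.random.Generator(np.random.PCG64(config.seed + 11))
    marker_probe = str(
        state["matrix"].probe_ids[rng.integers(state["matrix"].shape[0])]
    )
    marker = state["matrix"].values.loc[marker_probe]
    reports = stemness.discriminate_score_vs_marker(state["scores"], marker, labels)
    summary = {
        "marker_probe": marker_probe,
        **{
            key: {
                "auc": rep.auc,
                "p_value": rep.p_value,
                "fully_separated": rep.fully_separated,
            }
            for key, rep in reports.items()
        },
    }
    (out / "discrimination.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_diffexpr(config: RunConfig, state: dict, out: Path) -> dict:
    result = de.altered_gene_list(
        state["paired_matrix"],
        state["paired_annotation"],
        group_a="pre",
        group_b="post",
        fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
        paired=True,
        test="t_two_tailed",
    )
    summary = de.summarize_list(result)
    result.to_csv(out / "diffexpr.csv", index_label="probe_id")
    if summary["gene_set"] is not None:
        write_gmt([summary["gene_set"]], out / "altered_genes.gmt")
    state["de_summary"] = summary
    return {
        "n_up": summary["n_up"],
        "n_down": summary["n_down"],
        "n_passing": summary["n_passing"],
        "fc_threshold": config.fc_threshold,
        "p_threshold": config.p_threshold,
    }


def _stage_pca(config: RunConfig, state: dict, out: Path) -> dict:
    gene_set = state["de_summary"]["gene_set"]
    if gene_set is None or len(gene_set) < 3:
        raise ValueError("too few treatment-altered probes for a PCA embedding")
    embedding = ps.pca_embed(
        state["paired_matrix"], gene_set, n_components=3, transform=config.transform
    )
    annot = state["paired_annotation"].table
    labels = pd.Series(
        annot["group_label"].to_numpy(), index=annot["sample_id"].tolist()
    )
    separation = ps.cluster_separation(embedding, labels)
    embedding.coordinates.to_csv(out / "pca_embedding.csv", index_label="sample_id")
    (out / "pca_separation.json").write_text(json.dumps(separation, indent=2))
    return {
        "n_probes_used": len(gene_set),
        "explained_variance_fraction": [
            float(v) for v in embedding.explained_variance_fraction
        ],
        "mean_silhouette": separation["mean_silhouette"],
    }


def _stage_trend(config: RunConfig, state: dict, out: Path) -> dict:
    # treatment-similarity axis: profile averaged over the highest-scoring
    # non-reference samples (a stem-like "post-treatment" surrogate profile)
    scores = state["scores"]
    truth = state["truth"]
    bulk_scores = scores[~scores["sample_id"].isin(truth.reference_ids)]
    top = bulk_scores.nlargest(config.n_treatment_reference, "r")["sample_id"].tolist()
    profile = stemness.build_reference_profile(state["matrix"], top)
    treat_scores = stemness.score_samples(
        state["matrix"], profile, transform=config.transform
    )
    fits = ps.relatedness_analysis(scores, treat_scores, split="median")
    summary = {
        lab: {"a": f.a, "b": f.b, "r_fit": f.r_fit, "n": f.n}
        for lab, f in fits.items()
    }
    summary["treatment_reference_ids"] = top
    (out / "trend.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_heterogeneity(config: RunConfig, state: dict, out: Path) -> dict:
    subset = state["truth"].subset_gene_set(config.synthetic.subset_name)
    result = het.heterogeneity_profile(
        state["matrix"],
        state["scores"],
        n_groups=config.n_groups,
        subset=subset,
        transform=config.transform,
        permutation_null=True,
        permutation_seed=config.seed + 17,
    )
    result.table.to_csv(out / "heterogeneity.csv", index=False)
    tests = {
        "per_group": result.per_group_tests,
        "pooled": result.pooled_test,
        "pooled_permutation": result.pooled_permutation_test,
    }
    (out / "heterogeneity_tests.json").write_text(json.dumps(tests, indent=2))
    return {
        "n_groups": config.n_groups,
        "pooled_p_value": result.pooled_test["p_value"],
        "pooled_mean_difference": result.pooled_test["mean_difference"],
        "pooled_permutation_p_value": result.pooled_permutation_test["p_value"],
        "table": result.table.to_dict(orient="records"),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "discriminate": _stage_discriminate,
    "diffexpr": _stage_diffexpr,
    "pca": _stage_pca,
    "trend": _stage_trend,
    "heterogeneity": _stage_heterogeneity,
}
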