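"""End-to-end orchestration: simulate/ingest -> normalize -> marker models
-> transcriptomic grade -> subtyping -> CNV -> actionability -> report.

Every stage is deterministic given the run configuration and its seed
(one global seed expanded into per-stage streams); re-running an
identical configuration reproduces every reported number.  The report
bundle is persisted as TSV/JSON tables stamped with a schema version and
the run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import actionability as act
from . import clinical as clin
from . import cnv as cnvmod
from .exceptions import ConfigurationError
from .expression import ExpressionMatrix, normalize_log_cpm, read_expression
from .grade import TgCvConfig, classify_tg, fit_tg_model, reclassification_table
from .markers import (MARKER_GENE, ModelSpec, auc_confidence_interval, auc_score,
                      nested_cv_scores, optimal_boundary, roc_points)
from .stats import group_association, mean_difference_test
from .subtypes import classify_nsc, train_nsc
from .synthetic import (ERBB2_REGION, CohortConfig, generate_cohort, read_clinical,
                        read_cohort_bins, write_cohort)

SCHEMA_VERSION = "1"
log = logging.getLogger("seqdx")


@dataclass
class RunConfig:
    """Either a simulate block or explicit input paths (not both)."""

    simulate: Optional[CohortConfig] = None
    expression_path: Optional[str] = None
    clinical_path: Optional[str] = None
    alterations_path: Optional[str] = None  # MAF-like TSV
    bins_path: Optional[str] = None  # wide cohort bins TSV
    kb_path: Optional[str] = None  # defaults to packaged toy KB
    reexam_path: Optional[str] = None  # defaults to packaged discordant-case table
    outer_k: int = 5
    inner_k: int = 5
    n_lambda: int = 20
    nsc_delta: float = 0.0
    scope: str = "breast_only"
    seed: int = 0
    outdir: Optional[str] = None

    def validate(self) -> None:
        has_paths = any([self.expression_path, self.clinical_path,
                         self.alterations_path, self.bins_path])
        if self.simulate is not None and has_paths:
            raise ConfigurationError("config has both a simulate block and input paths")
        if self.simulate is None and not (self.expression_path and self.clinical_path):
            raise ConfigurationError(
                "config needs either a simulate block or expression and clinical paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = CohortConfig(**sim)
        return cfg


@dataclass
class ReportBundle:
    seed: int
    schema_version: str
    marker_report: pd.DataFrame
    marker_scores: pd.DataFrame
    tg_summary: dict
    reclassification: pd.DataFrame
    subtype_calls: Optional[pd.Series]
    subtype_tables: dict
    group_stats: dict
    cnv_calls: pd.DataFrame
    concordance: Optional[pd.DataFrame]
    actionability_summary: dict
    key_gene_flags: pd.DataFrame


def run_pipeline(config: RunConfig) -> ReportBundle:
    config.validate()
    rng_seed = config.seed

    # -- ingest / simulate ------------------------------------------------
    truth = None
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        expression, clinical = cohort.expression, cohort.clinical
        alterations = act.alterations_from_frame(cohort.alterations)
        bins, tumor_bins, baseline_bins = cohort.bins, cohort.tumor_bins, cohort.baseline_bins
        truth = cohort.truth
        log.info("stage=simulate n_samples=%d n_genes=%d", expression.n_samples,
                 expression.n_genes)
    else:
        expression = read_expression(config.expression_path)
        clinical = read_clinical(config.clinical_path)
        alterations = (act.read_alterations_maf(config.alterations_path)
                       if config.alterations_path else [])
        if config.bins_path:
            bins, tumor_bins, baseline_bins = read_cohort_bins(config.bins_path)
        else:
            bins = tumor_bins = baseline_bins = None
        log.info("stage=ingest n_samples=%d n_genes=%d", expression.n_samples,
                 expression.n_genes)
    clinical = clin.read_clinical_statuses(clinical)
    samples = expression.sample_ids

    # -- normalize --------------------------------------------------------
    normalized = normalize_log_cpm(expression)
    log.info("stage=normalize scale=%s", normalized.scale)

    # -- marker models ----------------------------------------------------
    marker_rows, score_cols = [], {}
    for marker, gene in MARKER_GENE.items():
        labels = clinical[f"{marker.lower()}_status"].loc[samples]
        scores, _ = nested_cv_scores(normalized, labels,
                                     ModelSpec(kind="single_gene_logistic", gene=gene),
                                     outer_k=config.outer_k, inner_k=config.inner_k,
                                     seed=rng_seed)
        marker_rows.append(_marker_row(marker, scores, labels))
        score_cols[marker] = scores
    ki67_pct = clinical["ki67_percent"].loc[samples].astype(float)
    ki67_scores, _ = nested_cv_scores(
        normalized, ki67_pct,
        ModelSpec(kind="elastic_net", family="linear", n_lambda=config.n_lambda),
        outer_k=config.outer_k, inner_k=config.inner_k, seed=rng_seed)
    ki67_labels = (ki67_pct >= clin.KI67_HIGH_THRESHOLD).map({True: "high", False: "low"})
    marker_rows.append(_marker_row("KI67", ki67_scores, ki67_labels))
    score_cols["KI67"] = ki67_scores
    marker_report = pd.DataFrame(marker_rows).set_index("marker")
    marker_scores = pd.DataFrame(score_cols)
    log.info("stage=markers aucs=%s", dict(zip(marker_report.index,
                                               marker_report["auc"].round(3))))

    # -- transcriptomic grade --------------------------------------------
    sub_scores = clinical.rename(columns={
        "mitotic_score": "mitotic", "nuclear_atypia_score": "nuclear_atypia",
        "tubular_formation_score": "tubular_formation"})[
        ["mitotic", "nuclear_atypia", "tubular_formation"]].loc[samples]
    grades = clinical["grade"].loc[samples]
    tg_model = fit_tg_model(normalized, sub_scores, grades,
                            TgCvConfig(outer_k=config.outer_k, inner_k=config.inner_k,
                                       n_lambda=config.n_lambda, seed=rng_seed))
    tg_auc = auc_score(tg_model.cv_scores.to_numpy(),
                       tg_model.cv_labels.to_numpy())
    tg_calls = classify_tg(tg_model, normalized)
    reclass = reclassification_table(tg_model, normalized, grades)
    tg_summary = {"auc_grade1_vs_3": tg_auc, "score_boundary": tg_model.score_boundary,
                  "grade2_split": reclass.grade2_split}
    log.info("stage=tg auc=%.3f boundary=%.3f", tg_auc, tg_model.score_boundary)

    # -- subtyping --------------------------------------------------------
    subtype_calls, subtype_tables, group_stats = None, {}, {}
    if truth is not None and "subtype" in truth.columns:
        nsc = train_nsc(normalized, truth["subtype"].loc[samples], delta=config.nsc_delta)
        subtype_calls, _ = classify_nsc(nsc, normalized)
        subtype_tables = {
            "by_grade": pd.crosstab(grades, subtype_calls),
            "by_tg": pd.crosstab(tg_calls, subtype_calls),
        }
        group_stats.update(_tg_group_stats(subtype_calls, tg_calls, grades, ki67_pct))
        log.info("stage=subtype distribution=%s", subtype_calls.value_counts().to_dict())

    # -- CNV --------------------------------------------------------------
    cnv_rows = []
    if bins is not None:
        gene_regions = [("ERBB2", *ERBB2_REGION)]
        for s in samples:
            tb = bins.assign(count=tumor_bins[s].to_numpy())
            bb = bins.assign(count=baseline_bins[s].to_numpy())
            profile = cnvmod.bin_log_ratio(tb, bb)
            for call in cnvmod.gene_cnv_call(profile, gene_regions):
                cnv_rows.append({"sample_id": s, "gene": call.gene,
                                 "mean_ratio": call.mean_ratio, "category": call.category})
        log.info("stage=cnv n_calls=%d", len(cnv_rows))
    cnv_calls = pd.DataFrame(cnv_rows, columns=["sample_id", "gene", "mean_ratio", "category"])

    # -- actionability ----------------------------------------------------
    her2_map = {s: ("positive" if v == "+" else "negative")
                for s, v in clinical["her2_status"].items()}
    kb = act.load_knowledge_base(config.kb_path)
    matches = act.match_patient(alterations, kb, scope=config.scope, her2_status=her2_map)
    best = act.best_match_per_patient(matches)
    actionability_summary = act.summarize_cohort(best, alterations, cohort_size=len(samples))
    flags = act.flag_key_genes(alterations, her2_map)
    log.info("stage=actionability matched=%d/%d", actionability_summary["n_matched"],
             len(samples))

    # -- concordance ------------------------------------------------------
    reexam = clin.load_reexam_records(config.reexam_path)
    concordance = clin.reexam_concordance(reexam).per_marker
    log.info("stage=concordance %s", concordance["percentage"].round(1).to_dict())

    bundle = ReportBundle(
        seed=config.seed, schema_version=SCHEMA_VERSION,
        marker_report=marker_report, marker_scores=marker_scores,
        tg_summary=tg_summary, reclassification=reclass.counts,
        subtype_calls=subtype_calls, subtype_tables=subtype_tables,
        group_stats=group_stats, cnv_calls=cnv_calls, concordance=concordance,
        actionability_summary=actionability_summary, key_gene_flags=flags,
    )
    if config.outdir:
        write_report(bundle, config.outdir)
    return bundle


def _marker_row(marker: str, scores: pd.Series, labels: pd.Series) -> dict:
    auc, lo, hi = auc_confidence_interval(scores.to_numpy(), labels.to_numpy())
    curve = roc_points(scores.to_numpy(), labels.to_numpy())
    return {"marker": marker, "auc": auc, "ci_low": lo, "ci_high": hi,
            "boundary": optimal_boundary(curve)}


def _tg_group_stats(subtypes: pd.Series, tg_calls: pd.Series, grades: pd.Series,
                    ki67_pct: pd.Series) -> dict:
    """Fisher tests of subtype distributions (high TG vs HG3, low TG vs HG1)
    and Welch t-tests of Ki-67 between the matching groups."""
    out = {}
    classes = sorted(subtypes.unique())

    def counts(mask_a, mask_b):
        rows = []
        for mask in (mask_a, mask_b):
            rows.append([int(((subtypes == c) & mask).sum()) for c in classes])
        tab = np.array(rows)
        keep = tab.sum(axis=0) > 0
        return tab[:, keep]

    pairs = {"high_tg_vs_hg3": (tg_calls == "high", grades == 3),
             "low_tg_vs_hg1": (tg_calls == "low", grades == 1)}
    for name, (a, b) in pairs.items():
        tab = counts(a, b)
        if tab.shape[1] >= 2:
            out[f"fisher_subtype_{name}"] = group_association(tab)
        out[f"ttest_ki67_{name}"] = mean_difference_test(
            ki67_pct[a].to_numpy(), ki67_pct[b].to_numpy())
    return out


def write_report(bundle: ReportBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"schema_version": bundle.schema_version, "seed": bundle.seed}

    def dump_json(name, obj):
        (outdir / name).write_text(json.dumps({**stamp, **obj}, indent=2, default=_js))

    bundle.marker_report.assign(**stamp).to_csv(outdir / "marker_report.tsv", sep="\t")
    bundle.marker_scores.to_csv(outdir / "marker_scores.tsv", sep="\t")
    dump_json("tg_summary.json", bundle.tg_summary)
    bundle.reclassification.assign(**stamp).to_csv(outdir / "reclassification.tsv", sep="\t")
    if bundle.subtype_calls is not None:
        bundle.subtype_calls.to_frame().assign(**stamp).to_csv(
            outdir / "subtype_calls.tsv", sep="\t")
    dump_json("group_stats.json", bundle.group_stats)
    bundle.cnv_calls.assign(**stamp).to_csv(outdir / "cnv_calls.tsv", sep="\t", index=False)
    if bundle.concordance is not None:
        bundle.concordance.assign(**stamp).to_csv(outdir / "concordance.tsv", sep="\t")
    dump_json("actionability.json", bundle.actionability_summary)
    bundle.key_gene_flags.assign(**stamp).to_csv(outdir / "key_gene_flags.tsv",
                                                 sep="\t", index=False)


def _js(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
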