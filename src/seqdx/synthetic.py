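"""Synthetic breast-cancer cohort generator.

Emulates the statistical structure that the downstream diagnostics assume,
so the whole pipeline is testable without access to patient data:

* bimodal marker-gene expression (ESR1, PGR, ERBB2, MKI67) by receptor /
  proliferation status, with a configurable log2 shift between groups;
* three disjoint gene programs (mitotic count, nuclear atypia, tubular
  formation) whose mean expression scales linearly with the 1-3
  subcomponent score of the Nottingham grade;
* intrinsic-subtype centroid structure over a 50-gene panel;
* ERBB2-locus amplification in HER2-positive tumors, visible in low-pass
  binned read counts at a configurable tumor/baseline ratio;
* a configurable rate of discordance between recorded clinical labels and
  the latent molecular truth;
* a small somatic/germline alteration table (PIK3CA, ERBB2, BRCA1/2, ...)
  for the actionability stage.

Expression is simulated as Gaussian on the log2 scale around per-gene
baselines and exponentiated to abundances, matching the log-linear models
fitted downstream.  All randomness flows from a single seed through named
sub-streams, so identical configurations give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .expression import ExpressionMatrix, write_expression
from .subtypes import SUBTYPE_CLASSES, pam50_genes

MARKER_GENES = {"ER": "ESR1", "PR": "PGR", "HER2": "ERBB2", "KI67": "MKI67"}
GRADE_COMPONENTS = ("mitotic", "nuclear_atypia", "tubular_formation")
_PROGRAM_PREFIX = {"mitotic": "MITO", "nuclear_atypia": "NUCA", "tubular_formation": "TUBF"}

# Toy chromosome-17 coordinate frame for the low-pass CNV simulation.  The
# ERBB2 locus sits at its GRCh38-like position; the simulated amplicon
# extends beyond the gene body, as real ERBB2 amplicons do.
ERBB2_REGION = ("chr17", 39_687_000, 39_731_000)
_ERBB2_AMPLICON = ("chr17", 39_500_000, 39_950_000)

_DEFAULT_PREVALENCE = {"ER": 0.80, "PR": 0.70, "HER2": 0.15, "KI67": 0.50}
_DEFAULT_SUBTYPE_WEIGHTS = {"Basal": 0.15, "LumA": 0.45, "LumB": 0.25, "Her2": 0.15}
_DEFAULT_GRADE_WEIGHTS = {1: 0.20, 2: 0.40, 3: 0.40}

# Fixed alteration spectrum for the actionability stage: (gene, class,
# origin, protein_change, per-sample probability).  Frequencies follow the
# rough ordering seen in breast tumors (PIK3CA mutation most common,
# BRCA1/2 events rare).
_ALTERATION_SPECTRUM = [
    ("PIK3CA", "snv", "somatic", "H1047R", 0.30),
    ("FGF3", "amplification", "somatic", None, 0.14),
    ("TOP2A", "amplification", "somatic", None, 0.08),
    ("ERBB2", "snv", "somatic", "L755S", 0.016),
    ("BRCA1", "snv", "germline", "Q1756fs", 0.013),
    ("BRCA1", "snv", "somatic", "E23fs", 0.003),
    ("BRCA2", "snv", "somatic", "S1982fs", 0.013),
    ("BRCA2", "snv", "germline", "K3326*", 0.010),
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated cohort.

    ``marker_shift`` and ``grade_effect`` are in log2 expression units;
    ``noise_sd`` is the per-gene Gaussian noise on the log2 scale.
    ``discordance_rate`` is the fraction of samples whose recorded
    ER/PR/HER2 label is flipped relative to the molecular truth.
    ``grade2_mixture`` switches score-2 grade programs from the default
    intermediate level to a 50:50 per-sample mixture of grade-1-like and
    grade-3-like levels (an "intermediate phenotype" scenario).
    """

    n_samples: int = 400
    n_genes: int = 500
    marker_shift: float = 2.0
    noise_sd: float = 1.0
    prevalence: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_PREVALENCE))
    grade_program_size: int = 30
    grade_effect: float = 1.5
    subtype_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SUBTYPE_WEIGHTS)
    )
    grade_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_GRADE_WEIGHTS)
    )
    discordance_rate: float = 0.0
    grade2_mixture: bool = False
    cnv_bin_size: int = 100_000
    n_cnv_bins: int = 1000
    cnv_depth: float = 500.0
    erbb2_amp_ratio: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError(f"n_samples must be >= 2, got {self.n_samples}")
        panel = len(pam50_genes())
        n_named = panel + 3 * self.grade_program_size
        if self.n_genes < n_named:
            raise ConfigurationError(
                f"n_genes={self.n_genes} is smaller than the {n_named} structured genes "
                f"({panel} panel + 3 x {self.grade_program_size} program genes)"
            )
        for marker, p in self.prevalence.items():
            if marker not in MARKER_GENES:
                raise ConfigurationError(f"prevalence: unknown marker {marker!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence[{marker}]={p} outside [0, 1]")
        missing = set(MARKER_GENES) - set(self.prevalence)
        if missing:
            raise ConfigurationError(f"prevalence missing markers: {sorted(missing)}")
        if not 0.0 <= self.discordance_rate <= 1.0:
            raise ConfigurationError(
                f"discordance_rate={self.discordance_rate} outside [0, 1]"
            )
        for name, weights, keys in (
            ("subtype_weights", self.subtype_weights, set(SUBTYPE_CLASSES)),
            ("grade_weights", self.grade_weights, {1, 2, 3}),
        ):
            if set(weights) != keys:
                raise ConfigurationError(f"{name} keys must be {sorted(keys)}")
            if any(w < 0 for w in weights.values()):
                raise ConfigurationError(f"{name} contains a negative weight")
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 within 1e-9")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd={self.noise_sd} must be >= 0")
        if self.marker_shift < 0:
            raise ConfigurationError(f"marker_shift={self.marker_shift} must be >= 0")
        if self.cnv_bin_size <= 0:
            raise ConfigurationError(f"cnv_bin_size={self.cnv_bin_size} must be > 0")
        if self.n_cnv_bins < 1:
            raise ConfigurationError(f"n_cnv_bins={self.n_cnv_bins} must be >= 1")
        if self.cnv_depth <= 0:
            raise ConfigurationError(f"cnv_depth={self.cnv_depth} must be > 0")
        if self.erbb2_amp_ratio <= 0:
            raise ConfigurationError(f"erbb2_amp_ratio={self.erbb2_amp_ratio} must be > 0")


@dataclass
class SyntheticCohort:
    """In-memory cohort: expression, clinical labels, latent truth,
    alterations, and binned tumor/baseline read counts."""

    config: CohortConfig
    expression: ExpressionMatrix
    clinical: pd.DataFrame  # indexed by sample id: recorded labels
    truth: pd.DataFrame  # indexed by sample id: latent molecular states
    alterations: pd.DataFrame  # patient, gene, alteration_class, origin, protein_change
    bins: pd.DataFrame  # chrom, start, end
    tumor_bins: pd.DataFrame  # bins x samples integer counts
    baseline_bins: pd.DataFrame  # bins x samples integer counts

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.sample_ids)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = [
        "baselines", "status", "subtype", "grade", "noise",
        "mixture", "ki67", "discordance", "cnv", "alterations",
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _overall_grade(component_scores: np.ndarray) -> np.ndarray:
    """Elston-Ellis-like binning of the summed subcomponent scores:
    3-5 -> grade 1, 6-7 -> grade 2, 8-9 -> grade 3."""
    total = component_scores.sum(axis=1)
    return np.where(total <= 5, 1, np.where(total <= 7, 2, 3))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort; deterministic given ``config`` (incl. its seed)."""
    config.validate()
    rng = _streams(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]

    panel = pam50_genes()
    program_genes = {
        comp: [f"{_PROGRAM_PREFIX[comp]}{i + 1:03d}" for i in range(config.grade_program_size)]
        for comp in GRADE_COMPONENTS
    }
    structured = list(panel) + [g for comp in GRADE_COMPONENTS for g in program_genes[comp]]
    fillers = [f"G{i + 1:05d}" for i in range(config.n_genes - len(structured))]
    genes = structured + fillers

    # Latent truth -----------------------------------------------------
    status = {
        m: rng["status"].random(n) < config.prevalence[m] for m in ("ER", "PR", "HER2", "KI67")
    }
    subtype = rng["subtype"].choice(
        SUBTYPE_CLASSES, size=n, p=[config.subtype_weights[c] for c in SUBTYPE_CLASSES]
    )
    latent_grade = rng["grade"].choice(
        [1, 2, 3], size=n, p=[config.grade_weights[g] for g in (1, 2, 3)]
    )
    # Subcomponent scores jitter around the latent grade (most tumors score
    # the same on all three components, a minority one step off).
    jitter = rng["grade"].choice([-1, 0, 1], size=(n, 3), p=[0.1, 0.8, 0.1])
    comp_scores = np.clip(latent_grade[:, None] + jitter, 1, 3)
    overall = _overall_grade(comp_scores)
    # Per-sample mixture state for the grade-2 intermediate-phenotype mode:
    # a score-2 program sits at the grade-1-like or grade-3-like level.
    mixture_high = rng["mixture"].random(n) < 0.5

    # Expression on the log2 scale ------------------------------------
    baselines = rng["baselines"].uniform(3.0, 9.0, size=len(genes))
    log2 = np.tile(baselines[:, None], (1, n))
    gene_index = {g: i for i, g in enumerate(genes)}

    for marker, gene in MARKER_GENES.items():
        log2[gene_index[gene], status[marker]] += config.marker_shift

    # Subtype centroid offsets on the panel genes (marker genes excluded:
    # their class structure comes from receptor status above).
    centroid_genes = [g for g in panel if g not in MARKER_GENES.values()]
    offsets = rng["baselines"].normal(0.0, 1.0, size=(len(centroid_genes), len(SUBTYPE_CLASSES)))
    class_index = {c: k for k, c in enumerate(SUBTYPE_CLASSES)}
    subtype_col = np.array([class_index[s] for s in subtype])
    for gi, g in enumerate(centroid_genes):
        log2[gene_index[g]] += offsets[gi, subtype_col]

    for ci, comp in enumerate(GRADE_COMPONENTS):
        score = comp_scores[:, ci].astype(float)
        level = score - 2.0  # -1, 0, +1 around baseline
        if config.grade2_mixture:
            is2 = comp_scores[:, ci] == 2
            level = np.where(is2, np.where(mixture_high, 1.0, -1.0), level)
        shift = config.grade_effect * level
        for g in program_genes[comp]:
            log2[gene_index[g]] += shift

    log2 += rng["noise"].normal(0.0, config.noise_sd, size=log2.shape)
    expression = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2), index=genes, columns=samples), scale="raw"
    )

    # Ki-67 percent: logistic transform of the MKI67 deviation from the
    # midpoint between the negative and positive means (slope 2 per log2
    # unit), scaled to 0-100 %.  Noise in MKI67 expression carries through,
    # so recorded percent and latent status disagree for borderline tumors.
    mki67_dev = log2[gene_index["MKI67"]] - (baselines[gene_index["MKI67"]] + config.marker_shift / 2.0)
    ki67_pct = 100.0 / (1.0 + np.exp(-2.0 * mki67_dev))

    # Recorded clinical labels, with discordance flips ------------------
    recorded = {m: status[m].copy() for m in ("ER", "PR", "HER2")}
    n_flip = int(round(config.discordance_rate * n))
    for m in ("ER", "PR", "HER2"):
        if n_flip:
            idx = rng["discordance"].choice(n, size=n_flip, replace=False)
            recorded[m][idx] = ~recorded[m][idx]

    def pm(mask: np.ndarray) -> np.ndarray:
        return np.where(mask, "+", "-")

    clinical = pd.DataFrame(
        {
            "er_status": pm(recorded["ER"]),
            "pr_status": pm(recorded["PR"]),
            "her2_status": pm(recorded["HER2"]),
            "ki67_percent": np.round(ki67_pct, 4),
            "mitotic_score": comp_scores[:, 0],
            "nuclear_atypia_score": comp_scores[:, 1],
            "tubular_formation_score": comp_scores[:, 2],
            "grade": overall,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = pd.DataFrame(
        {
            "er_status": pm(status["ER"]),
            "pr_status": pm(status["PR"]),
            "her2_status": pm(status["HER2"]),
            "ki67_status": np.where(status["KI67"], "high", "low"),
            "subtype": subtype,
            "latent_grade": latent_grade,
            "mitotic_score": comp_scores[:, 0],
            "nuclear_atypia_score": comp_scores[:, 1],
            "tubular_formation_score": comp_scores[:, 2],
            "grade": overall,
            "grade2_program_high": mixture_high,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    # Low-pass CNV bins: the grid is anchored so the ERBB2 locus is always
    # covered, whatever the configured bin count and size.
    chrom, gene_start, _ = ERBB2_REGION
    span = config.n_cnv_bins * config.cnv_bin_size
    grid_start = max(0, gene_start - span // 2)
    grid_start -= grid_start % config.cnv_bin_size
    starts = grid_start + np.arange(config.n_cnv_bins, dtype=np.int64) * config.cnv_bin_size
    ends = starts + config.cnv_bin_size
    bins = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
    amp_mask = (starts < _ERBB2_AMPLICON[2]) & (ends > _ERBB2_AMPLICON[1])
    ratio = np.ones((config.n_cnv_bins, n))
    ratio[np.ix_(amp_mask, status["HER2"])] = config.erbb2_amp_ratio
    baseline_counts = rng["cnv"].poisson(config.cnv_depth, size=(config.n_cnv_bins, n))
    tumor_counts = rng["cnv"].poisson(config.cnv_depth * ratio)
    tumor_bins = pd.DataFrame(tumor_counts, columns=samples)
    baseline_bins = pd.DataFrame(baseline_counts, columns=samples)

    # Somatic / germline alterations ------------------------------------
    rows = []
    arng = rng["alterations"]
    fgf4_linked = None
    for gene, cls, origin, protein, prob in _ALTERATION_SPECTRUM:
        carriers = arng.random(n) < prob
        if gene == "ERBB2" and cls == "snv":
            # ERBB2 point mutations occur in tumors without HER2
            # overexpression, mirroring their clinical presentation.
            carriers &= ~status["HER2"]
        for i in np.nonzero(carriers)[0]:
            rows.append((samples[i], gene, cls, origin, protein))
        if gene == "FGF3":
            fgf4_linked = carriers  # FGF3/FGF4 co-amplify (adjacent loci)
    if fgf4_linked is not None:
        for i in np.nonzero(fgf4_linked)[0]:
            rows.append((samples[i], "FGF4", "amplification", "somatic", None))
    for i in np.nonzero(status["HER2"])[0]:
        rows.append((samples[i], "ERBB2", "amplification", "somatic", None))
    alterations = pd.DataFrame(
        rows, columns=["patient", "gene", "alteration_class", "origin", "protein_change"]
    ).sort_values(["patient", "gene", "alteration_class", "origin"], kind="stable")
    alterations = alterations.reset_index(drop=True)

    return SyntheticCohort(
        config=config,
        expression=expression,
        clinical=clinical,
        truth=truth,
        alterations=alterations,
        bins=bins,
        tumor_bins=tumor_bins,
        baseline_bins=baseline_bins,
    )


def write_cohort(cohort: SyntheticCohort, directory, include_truth: bool = False) -> dict[str, str]:
    """Write a cohort to ``directory``; returns a manifest of written files.

    Formats: expression TSV, clinical CSV, alterations as MAF-like TSV and
    as a minimal multi-sample VCF, and a wide BED-like bins TSV carrying
    tumor and baseline counts per sample.  The latent truth table is only
    written when ``include_truth`` is set (it is not an observable input).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}

    p = directory / "expression.tsv"
    write_expression(cohort.expression, p, float_format="%.8g")
    manifest["expression"] = str(p)

    p = directory / "clinical.csv"
    cohort.clinical.to_csv(p)
    manifest["clinical"] = str(p)

    p = directory / "alterations.maf.tsv"
    cohort.alterations.to_csv(p, sep="\t", index=False)
    manifest["alterations_maf"] = str(p)

    p = directory / "alterations.vcf"
    _write_alterations_vcf(cohort.alterations, cohort.sample_ids, p)
    manifest["alterations_vcf"] = str(p)

    p = directory / "bins.tsv"
    wide = pd.concat(
        [cohort.bins,
         cohort.tumor_bins.rename(columns=lambda s: f"tumor:{s}"),
         cohort.baseline_bins.rename(columns=lambda s: f"baseline:{s}")],
        axis=1)
    wide.to_csv(p, sep="\t", index=False)
    manifest["bins"] = str(p)

    if include_truth:
        p = directory / "truth.csv"
        cohort.truth.to_csv(p)
        manifest["truth"] = str(p)
    return manifest


def _write_alterations_vcf(alterations: pd.DataFrame, samples: list[str], path) -> None:
    """Minimal VCF v4.2: one record per distinct (gene, class, origin,
    protein_change) event, GT 0/1 for carriers, GENE/CLASS/ORIGIN/PCHANGE
    in INFO.  Positions are synthetic (stable per event)."""
    events = alterations.groupby(
        ["gene", "alteration_class", "origin", "protein_change"], dropna=False, sort=True
    )
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1,length=100000000>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Alteration class">',
        '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="somatic or germline">',
        '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##ALT=<ID=AMP,Description="Amplification">',
        '##ALT=<ID=DEL,Description="Deep deletion">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    sample_pos = {s: i for i, s in enumerate(samples)}
    for pos, ((gene, cls, origin, protein), grp) in enumerate(events, start=1):
        alt = {"amplification": "<AMP>", "deep_deletion": "<DEL>"}.get(cls, "T")
        info = f"GENE={gene};CLASS={cls};ORIGIN={origin}"
        if isinstance(protein, str) and protein:
            info += f";PCHANGE={protein}"
        gts = ["0/0"] * len(samples)
        for patient in grp["patient"]:
            gts[sample_pos[patient]] = "0/1"
        lines.append(
            f"1\t{pos * 1000}\t.\tA\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cohort_bins(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the wide bins TSV written by :func:`write_cohort`.

    Returns (bins, tumor_bins, baseline_bins) with bins as (chrom, start,
    end) and the count frames keyed by sample id.
    """
    wide = pd.read_csv(path, sep="\t")
    bins = wide[["chrom", "start", "end"]].copy()
    tumor = {c.split(":", 1)[1]: wide[c] for c in wide.columns if c.startswith("tumor:")}
    base = {c.split(":", 1)[1]: wide[c] for c in wide.columns if c.startswith("baseline:")}
    return bins, pd.DataFrame(tumor), pd.DataFrame(base)


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical CSV written by :func:`write_cohort`."""
    return pd.read_csv(path, index_col="sample_id")
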