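"""Matching somatic alterations to an actionability knowledge base.

Somatic SNVs, indels, amplifications and deep deletions are matched to
knowledge-base entries by gene and alteration class; germline events are
never matched (they are handled separately by :func:`flag_key_genes`).
When counting patients eligible for targeted therapy, each patient is
counted once, for the candidate drug of highest priority
(approved > late-phase > early-phase studies).

The packaged knowledge base is a 15-entry toy with the true schema of a
curated actionability database (gene, alteration class, therapy,
indication, phase, and an optional HER2-positive co-requirement for
combination-trial entries); its content is illustrative, not a
redistribution of any curated database.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

from .exceptions import ConfigurationError, DataFormatError

ALTERATION_CLASSES = ("snv", "indel", "amplification", "deep_deletion")
ORIGINS = ("somatic", "germline")
PHASES = ("approved", "late", "early")  # descending priority
_PHASE_RANK = {p: i for i, p in enumerate(PHASES)}
SCOPES = ("breast_only", "any_indication")


@dataclass(frozen=True)
class SomaticAlteration:
    patient: str
    gene: str
    alteration_class: str
    origin: str
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise DataFormatError("alteration with empty gene symbol")
        if self.alteration_class not in ALTERATION_CLASSES:
            raise DataFormatError(
                f"{self.patient}/{self.gene}: unknown alteration_class "
                f"{self.alteration_class!r}"
            )
        if self.origin not in ORIGINS:
            raise DataFormatError(
                f"{self.patient}/{self.gene}: unknown origin {self.origin!r}"
            )


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    gene: str
    alteration_class: str
    therapy: str
    indication: str  # breast | other
    phase: str  # approved | late | early
    requires_her2_positive: bool = False

    def __post_init__(self) -> None:
        if self.alteration_class not in ALTERATION_CLASSES:
            raise DataFormatError(
                f"KB entry {self.gene}/{self.therapy}: unknown alteration_class "
                f"{self.alteration_class!r}"
            )
        if self.phase not in PHASES:
            raise DataFormatError(
                f"KB entry {self.gene}/{self.therapy}: unknown phase {self.phase!r}"
            )
        if self.indication not in ("breast", "other"):
            raise DataFormatError(
                f"KB entry {self.gene}/{self.therapy}: indication must be breast/other"
            )


@dataclass(frozen=True)
class ActionabilityMatch:
    patient: str
    alteration: SomaticAlteration
    entry: KnowledgeBaseEntry


def load_knowledge_base(path=None) -> list[KnowledgeBaseEntry]:
    """Read a KB TSV (gene, alteration_class, therapy, indication, phase,
    optional requires_her2_positive); defaults to the packaged toy KB."""
    if path is None:
        with resources.as_file(resources.files("seqdx.data").joinpath("toy_kb.tsv")) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "alteration_class", "therapy", "indication", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"knowledge base missing columns: {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        req = getattr(row, "requires_her2_positive", "")
        entries.append(KnowledgeBaseEntry(
            gene=row.gene, alteration_class=row.alteration_class, therapy=row.therapy,
            indication=row.indication, phase=row.phase,
            requires_her2_positive=str(req).strip().lower() in ("yes", "true", "1"),
        ))
    return entries


def read_alterations_maf(path) -> list[SomaticAlteration]:
    """Read a MAF-like TSV (patient, gene, alteration_class, origin,
    protein_change)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"patient", "gene", "alteration_class", "origin"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"alteration table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        protein = getattr(row, "protein_change", "") or None
        out.append(SomaticAlteration(patient=row.patient, gene=row.gene,
                                     alteration_class=row.alteration_class,
                                     origin=row.origin, protein_change=protein))
    return out


def read_alterations_vcf(path) -> list[SomaticAlteration]:
    """Read alterations from a minimal VCF with GENE/CLASS/ORIGIN (and
    optional PCHANGE) INFO keys and per-sample genotypes; every sample
    with a non-reference genotype carries the record's alteration."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    out = []
    for variant in vcf:
        gene = variant.INFO.get("GENE")
        cls = variant.INFO.get("CLASS")
        origin = variant.INFO.get("ORIGIN")
        if gene is None or cls is None or origin is None:
            raise DataFormatError(
                f"VCF record at {variant.CHROM}:{variant.POS} lacks GENE/CLASS/ORIGIN INFO"
            )
        protein = variant.INFO.get("PCHANGE")
        for i, gt in enumerate(variant.gt_types):
            if gt in (1, 3):  # het or hom-alt
                out.append(SomaticAlteration(patient=samples[i], gene=gene,
                                             alteration_class=cls, origin=origin,
                                             protein_change=protein))
    vcf.close()
    return out


def alterations_from_frame(df: pd.DataFrame) -> list[SomaticAlteration]:
    """Convert a (patient, gene, alteration_class, origin, protein_change)
    DataFrame into alteration records."""
    out = []
    for row in df.itertuples(index=False):
        protein = row.protein_change if isinstance(row.protein_change, str) and row.protein_change else None
        out.append(SomaticAlteration(patient=row.patient, gene=row.gene,
                                     alteration_class=row.alteration_class,
                                     origin=row.origin, protein_change=protein))
    return out


def match_patient(alterations: Iterable[SomaticAlteration],
                  kb: Iterable[KnowledgeBaseEntry], scope: str = "breast_only",
                  her2_status: Optional[Mapping[str, str]] = None) -> list[ActionabilityMatch]:
    """Match somatic alterations to KB entries by gene and class.

    ``scope="breast_only"`` restricts to breast-indication entries and
    additionally excludes the ERBB2-amplification entry (routine IHC/ISH
    already captures HER2 amplification, so it adds no sequencing-specific
    actionability).  Germline alterations are never matched.  Entries with
    a HER2-positive co-requirement match only patients whose HER2 status
    (from ``her2_status``) is "positive".
    """
    if scope not in SCOPES:
        raise ConfigurationError(f"scope must be one of {SCOPES}, got {scope!r}")
    kb = list(kb)
    matches = []
    for alt in alterations:
        if alt.origin != "somatic":
            continue
        for entry in kb:
            if entry.gene != alt.gene or entry.alteration_class != alt.alteration_class:
                continue
            if scope == "breast_only":
                if entry.indication != "breast":
                    continue
                if entry.gene == "ERBB2" and entry.alteration_class == "amplification":
                    continue
            if entry.requires_her2_positive:
                status = (her2_status or {}).get(alt.patient)
                if status not in ("positive", "+"):
                    continue
            matches.append(ActionabilityMatch(patient=alt.patient, alteration=alt, entry=entry))
    return matches


def best_match_per_patient(matches: Iterable[ActionabilityMatch]) -> list[ActionabilityMatch]:
    """Keep at most one match per patient: highest phase priority first,
    ties broken by (gene, therapy) lexicographic order."""
    best: dict[str, ActionabilityMatch] = {}
    for m in matches:
        key = (_PHASE_RANK[m.entry.phase], m.entry.gene, m.entry.therapy)
        cur = best.get(m.patient)
        if cur is None or key < (_PHASE_RANK[cur.entry.phase], cur.entry.gene, cur.entry.therapy):
            best[m.patient] = m
    return [best[p] for p in sorted(best)]


def summarize_cohort(best_matches: Iterable[ActionabilityMatch],
                     alterations: Iterable[SomaticAlteration],
                     cohort_size: int) -> dict:
    """Patient counts by phase and by matched alteration kind.

    ``best_matches`` must already be deduplicated per patient.  Alteration
    kinds split SNV/indel vs amplification/deep-deletion, counting a
    patient under a kind if their best match is of that kind.
    """
    best = list(best_matches)
    patients = [m.patient for m in best]
    if len(set(patients)) != len(patients):
        raise ConfigurationError("best_matches contains duplicate patients")
    phase_counts = {p: 0 for p in PHASES}
    kind_counts = {"snv_indel": 0, "cnv": 0}
    for m in best:
        phase_counts[m.entry.phase] += 1
        if m.alteration.alteration_class in ("snv", "indel"):
            kind_counts["snv_indel"] += 1
        else:
            kind_counts["cnv"] += 1
    n_matched = len(best)
    return {
        "n_matched": n_matched,
        "cohort_size": cohort_size,
        "pct_matched": 100.0 * n_matched / cohort_size if cohort_size else float("nan"),
        "by_phase": phase_counts,
        "by_kind": kind_counts,
    }


def flag_key_genes(alterations: Iterable[SomaticAlteration],
                   her2_status_per_patient: Mapping[str, str]) -> pd.DataFrame:
    """Flag clinically notable events outside routine biomarkers.

    Flag A: somatic ERBB2 SNV/indel in a HER2-negative patient (HER2
    signaling may be activated without overexpression; candidates for
    kinase-inhibitor discussion).  Flag B: any BRCA1/BRCA2 alteration,
    annotated with its somatic/germline origin.  Alterations for patients
    without a recorded HER2 status are flagged with status "missing".
    """
    rows = []
    neg = ("negative", "-")
    for alt in alterations:
        if alt.gene == "ERBB2" and alt.origin == "somatic" and \
                alt.alteration_class in ("snv", "indel"):
            status = her2_status_per_patient.get(alt.patient, "missing")
            if status == "missing" or status in neg:
                rows.append({"patient": alt.patient, "flag": "A",
                             "gene": "ERBB2", "origin": alt.origin,
                             "protein_change": alt.protein_change,
                             "her2_status": "missing" if status == "missing" else "negative"})
        if alt.gene in ("BRCA1", "BRCA2"):
            rows.append({"patient": alt.patient, "flag": "B", "gene": alt.gene,
                         "origin": alt.origin, "protein_change": alt.protein_change,
                         "her2_status": her2_status_per_patient.get(alt.patient, "missing")})
    return pd.DataFrame(rows, columns=["patient", "flag", "gene", "origin",
                                       "protein_change", "her2_status"])
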