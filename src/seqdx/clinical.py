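"""Routine clinical biomarker rules and re-examination concordance.

Status rules as used in Swedish routine pathology of the study period:

* ER / PR: positive if IHC staining in >= 10% of cells, or (older
  radioimmunoassay samples) > 0.05 fmol/ug DNA.  IHC is preferred when
  both assays are present.
* HER2: positive if in-situ hybridization (FISH/SISH) shows amplification;
  in the absence of an ISH result, positive iff IHC grade is 3+.
* Ki-67: high if >= 20% positively stained cells (the threshold value
  itself counts as high); categorical "high"/"low" records pass through.

Re-examination concordance: for tumors whose sequencing-based receptor
call disagreed with the medical record, pathology re-examination may
revise the status.  A patient counts as "reclassified and concordant"
for a marker when any re-examined tumor piece has a re-examined status
that differs from the medical record AND equals the sequencing-based
call; denominators count distinct re-examined patients per marker, and
multi-piece patients are counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .exceptions import ConfigurationError, DataFormatError

POSITIVE = "positive"
NEGATIVE = "negative"
MISSING = "missing"

ER_IHC_PERCENT_THRESHOLD = 10.0
ER_RIA_THRESHOLD = 0.05  # fmol/ug DNA, strict inequality
KI67_HIGH_THRESHOLD = 20.0  # percent, inclusive


@dataclass
class AssayRecord:
    patient: str
    marker: str  # ER | PR | HER2 | Ki67
    ihc_percent: Optional[float] = None
    ria_value: Optional[float] = None
    ihc_grade: Optional[str] = None  # "0" | "1+" | "2+" | "3+"
    ish_result: Optional[str] = None  # "amplified" | "not_amplified"

    def __post_init__(self) -> None:
        if all(v is None for v in (self.ihc_percent, self.ria_value,
                                   self.ihc_grade, self.ish_result)):
            raise DataFormatError(f"{self.patient}/{self.marker}: no assay field present")
        if self.ihc_percent is not None and not 0.0 <= self.ihc_percent <= 100.0:
            raise DataFormatError(
                f"{self.patient}/{self.marker}: ihc_percent {self.ihc_percent} outside [0, 100]"
            )


@dataclass
class ReexamRecord:
    """One re-examined tumor piece for one discordant marker."""

    patient: str
    marker: str  # ER | HER2
    piece: str = ""
    medical_status: str = MISSING
    sequencing_status: str = MISSING
    reexamined_status: str = MISSING
    cnv_annotation: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("medical_status", "sequencing_status", "reexamined_status"):
            v = getattr(self, name)
            if v not in (POSITIVE, NEGATIVE, MISSING):
                raise DataFormatError(
                    f"{self.patient}/{self.marker}: {name}={v!r} not in "
                    f"{{positive, negative, missing}}"
                )


@dataclass
class ConcordanceSummary:
    """Per-marker counts of re-examined patients and of those reclassified
    to agree with the sequencing-based call."""

    per_marker: pd.DataFrame  # index marker; columns n_reexamined, n_reclassified_concordant, percentage


def er_status(record: AssayRecord) -> str:
    """ER (or PR) status: IHC >= 10% positive, else RIA > 0.05 fmol/ug."""
    if record.ihc_percent is not None:
        return POSITIVE if record.ihc_percent >= ER_IHC_PERCENT_THRESHOLD else NEGATIVE
    if record.ria_value is not None:
        return POSITIVE if record.ria_value > ER_RIA_THRESHOLD else NEGATIVE
    raise DataFormatError(f"{record.patient}: neither IHC percent nor RIA value present")


pr_status = er_status  # same thresholds apply to PR


def her2_status(record: AssayRecord) -> str:
    """HER2 status: ISH amplification decides when present; otherwise IHC 3+."""
    if record.ish_result is not None:
        if record.ish_result == "amplified":
            return POSITIVE
        if record.ish_result == "not_amplified":
            return NEGATIVE
        raise DataFormatError(
            f"{record.patient}: ish_result must be amplified/not_amplified, "
            f"got {record.ish_result!r}"
        )
    if record.ihc_grade is not None:
        return POSITIVE if record.ihc_grade == "3+" else NEGATIVE
    raise DataFormatError(f"{record.patient}: neither ISH result nor IHC grade present")


def ki67_status(value) -> str:
    """Ki-67 high/low: percent >= 20 is high; categorical passes through."""
    if value is None:
        raise DataFormatError("Ki-67 value missing")
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("high", "low"):
            return v
        try:
            value = float(v)
        except ValueError:
            raise DataFormatError(f"unrecognized Ki-67 value {value!r}") from None
    return "high" if float(value) >= KI67_HIGH_THRESHOLD else "low"


def reexam_concordance(records: Iterable[ReexamRecord]) -> ConcordanceSummary:
    """Per-marker re-examination concordance over patients (see module
    docstring for the any-piece rule)."""
    records = list(records)
    by_marker: dict[str, dict[str, list[ReexamRecord]]] = {}
    for r in records:
        if r.reexamined_status == MISSING:
            continue
        if r.sequencing_status == MISSING:
            raise DataFormatError(
                f"{r.patient}/{r.marker}: re-examined piece lacks a sequencing-based status"
            )
        by_marker.setdefault(r.marker, {}).setdefault(r.patient, []).append(r)
    rows = []
    for marker in sorted(by_marker):
        patients = by_marker[marker]
        n = len(patients)
        n_ok = 0
        for pieces in patients.values():
            ok = any(
                p.reexamined_status != p.medical_status
                and p.reexamined_status == p.sequencing_status
                for p in pieces
                if p.medical_status != MISSING
            )
            n_ok += int(ok)
        rows.append({"marker": marker, "n_reexamined": n,
                     "n_reclassified_concordant": n_ok,
                     "percentage": 100.0 * n_ok / n if n else float("nan")})
    df = pd.DataFrame(rows, columns=["marker", "n_reexamined",
                                     "n_reclassified_concordant", "percentage"])
    return ConcordanceSummary(per_marker=df.set_index("marker") if len(df) else df)


def _pm(value: str) -> str:
    return {"+": POSITIVE, "-": NEGATIVE}.get(str(value).strip(), MISSING)


def load_reexam_records(path=None) -> list[ReexamRecord]:
    """Load re-examination records from CSV; defaults to the packaged
    discordant-case table (transcribed verbatim, including NA cells)."""
    if path is None:
        with resources.as_file(
            resources.files("seqdx.data").joinpath("table1_reexam.csv")
        ) as p:
            df = pd.read_csv(p, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        markers = str(row.discordant_markers).split("/")
        for marker in markers:
            mr = row.mr_er if marker == "ER" else row.mr_her2
            seq = row.seq_er if marker == "ER" else row.seq_her2
            rex = row.reexam_er if marker == "ER" else row.reexam_her2
            records.append(ReexamRecord(
                patient=row.patient_id, marker=marker, piece=row.piece,
                medical_status=_pm(mr), sequencing_status=_pm(seq),
                reexamined_status=_pm(rex),
                cnv_annotation=row.her2_copy_number or None,
            ))
    return records


def read_clinical_statuses(clinical: pd.DataFrame) -> pd.DataFrame:
    """Normalize a clinical table to positive/negative/high/low statuses.

    Expects columns er_status, pr_status, her2_status (+/-) and
    ki67_percent; adds a derived ki67_status column.
    """
    out = clinical.copy()
    for col in ("er_status", "pr_status", "her2_status"):
        if col in out.columns:
            bad = set(out[col].unique()) - {"+", "-"}
            if bad:
                raise DataFormatError(f"{col}: unrecognized values {sorted(bad)}")
    if "ki67_percent" in out.columns:
        out["ki67_status"] = [ki67_status(v) for v in out["ki67_percent"]]
    return out
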