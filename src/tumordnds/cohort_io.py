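"""Reading and normalising cohort tables (MAF-like mutations, clinical, sample meta).

Input tables are tab-separated with a header; lines starting with ``#`` are
ignored (MAF convention).  Every mutation row is mapped onto a
:class:`MutationRecord` whose functional class is derived deterministically
from the original annotation label: point substitutions that change the
protein are ``nonsilent``, synonymous substitutions are ``silent``, and
everything else (indels, splice, UTR, intron, ...) is ``other`` and excluded
from dN/dS, since point-substitution dN/dS theory does not cover it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml


class CohortFormatError(ValueError):
    """Malformed input file (missing column, bad header, ...)."""


class CohortValidationError(ValueError):
    """Well-formed file with invalid values."""


class VariantClass(str, Enum):
    NONSILENT = "nonsilent"
    SILENT = "silent"
    OTHER = "other"


class SampleStatus(str, Enum):
    BENIGN = "benign"
    PRIMARY = "primary"
    METASTASIS = "metastasis"
    PRE_TREATMENT = "pre_treatment"
    POST_TREATMENT = "post_treatment"
    RELAPSE = "relapse"
    OTHER = "other"


#: Annotation labels counted as protein-changing point substitutions.  The
#: published multi-sample cohorts differ in whether nonsense mutations enter
#: the nonsilent count; they are included here by default (a nonsense
#: substitution is protein-changing) and can be excluded via
#: :func:`default_class_map`.
NONSILENT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Translation_Start_Site",
)
SILENT_CLASSES = ("Silent", "Synonymous")


def default_class_map(include_nonsense: bool = True) -> dict[str, VariantClass]:
    """Default raw-label → variant-class mapping.

    ``include_nonsense=False`` reassigns ``Nonsense_Mutation`` to ``other``
    for cohorts whose published counts excluded nonsense mutations.
    """
    mapping = {label: VariantClass.NONSILENT for label in NONSILENT_CLASSES}
    mapping.update({label: VariantClass.SILENT for label in SILENT_CLASSES})
    if not include_nonsense:
        mapping["Nonsense_Mutation"] = VariantClass.OTHER
    return mapping


def load_class_map(path: str | Path) -> dict[str, VariantClass]:
    """Load a YAML class map ``{raw_label: nonsilent|silent|other}``."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, Mapping):
        raise CohortFormatError(f"class map {path} must be a mapping")
    return {str(k): VariantClass(str(v)) for k, v in raw.items()}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic point mutation."""

    patient_id: str
    sample_id: str
    gene: str
    variant_class: VariantClass
    allele_frequency: float | None = None
    raw_class: str = ""
    #: Most specific identity available for cross-sample matching
    #: (genomic position or protein change when the input provides one).
    position_key: str | None = None

    def __post_init__(self) -> None:
        af = self.allele_frequency
        if af is not None and not (0.0 <= af <= 1.0):
            raise CohortValidationError(
                f"allele frequency {af} outside [0, 1] for {self.gene}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical/technical annotations."""

    patient_id: str
    sample_id: str
    status: SampleStatus = SampleStatus.OTHER
    timepoint: float | None = None
    tumor_purity: float | None = None
    msi_score: float | None = None
    cna_fraction: float | None = None


@dataclass(frozen=True)
class ClinicalRecord:
    """Censored time-to-event outcome with drug-exposure indicators."""

    patient_id: str
    survival_time: float  # months
    event: bool  # True = death/progression observed, False = censored
    drugs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.survival_time > 0:
            raise CohortValidationError(
                f"survival time must be positive, got {self.survival_time}"
            )


_MAF_REQUIRED = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


def _optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_maf(
    path: str | Path,
    class_map: Mapping[str, VariantClass] | None = None,
) -> list[MutationRecord]:
    """Read a MAF-like TSV into mutation records.

    Requires ``Hugo_Symbol``, ``Variant_Classification`` and
    ``Tumor_Sample_Barcode`` columns.  ``Patient_ID`` is used when present,
    otherwise the sample barcode doubles as the patient identifier.  Allele
    frequency is taken from an ``AF`` column, or computed as
    ``t_alt_count / (t_alt_count + t_ref_count)`` when read counts are given.
    Rows whose class label is not in the map are labelled ``other``.
    """
    if class_map is None:
        class_map = default_class_map()
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for column in _MAF_REQUIRED:
        if column not in frame.columns:
            raise CohortFormatError(f"{path}: missing required column {column!r}")

    has_patient = "Patient_ID" in frame.columns
    has_af = "AF" in frame.columns
    has_counts = "t_alt_count" in frame.columns and "t_ref_count" in frame.columns
    key_columns = [
        c for c in ("Chromosome", "Start_Position", "Reference_Allele",
                    "Tumor_Seq_Allele2", "HGVSp_Short")
        if c in frame.columns
    ]

    records: list[MutationRecord] = []
    for row in frame.itertuples(index=True):
        line_no = row.Index + 2  # 1-based, after the header line
        data = row._asdict()
        sample_id = data["Tumor_Sample_Barcode"]
        patient_id = data["Patient_ID"] if has_patient else sample_id
        raw_class = data["Variant_Classification"]
        af: float | None = None
        if has_af:
            try:
                af = _optional_float(data["AF"])
            except (TypeError, ValueError) as exc:
                raise CohortValidationError(
                    f"{path}, line {line_no}: non-numeric AF"
                ) from exc
        elif has_counts:
            try:
                alt = _optional_float(data["t_alt_count"])
                ref = _optional_float(data["t_ref_count"])
            except (TypeError, ValueError) as exc:
                raise CohortValidationError(
                    f"{path}, line {line_no}: non-numeric read counts"
                ) from exc
            if alt is not None and ref is not None and alt + ref > 0:
                af = alt / (alt + ref)
        position_key = None
        if key_columns:
            parts = [str(data[c]) for c in key_columns if not pd.isna(data[c])]
            if parts:
                position_key = ":".join(parts)
        records.append(
            MutationRecord(
                patient_id=str(patient_id),
                sample_id=str(sample_id),
                gene=str(data["Hugo_Symbol"]),
                variant_class=class_map.get(raw_class, VariantClass.OTHER),
                allele_frequency=af,
                raw_class=str(raw_class),
                position_key=position_key,
            )
        )
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records back to a minimal MAF-like TSV (round-trips with read_maf)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "Hugo_Symbol": rec.gene,
                "Variant_Classification": rec.raw_class or rec.variant_class.value,
                "Tumor_Sample_Barcode": rec.sample_id,
                "Patient_ID": rec.patient_id,
                "AF": "" if rec.allele_frequency is None else rec.allele_frequency,
                "HGVSp_Short": rec.position_key or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical TSV (patient, survival time, event, drug indicators).

    Columns named ``drug_*`` (or ``drug*``) are interpreted as 0/1 exposure
    indicators and collected into each record's ``drugs`` set; an ``event``
    value outside {0, 1} is a validation error.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    for column in ("Patient_ID", "survival_time", "event"):
        if column not in frame.columns:
            raise CohortFormatError(f"{path}: missing required column {column!r}")
    drug_columns = [c for c in frame.columns if c.lower().startswith("drug")]
    records = []
    for _, row in frame.iterrows():
        event = row["event"]
        if event not in (0, 1):
            raise CohortValidationError(
                f"{path}: event must be 0 or 1, got {event!r} "
                f"for patient {row['Patient_ID']}"
            )
        drugs = frozenset(c for c in drug_columns if int(row[c]) == 1)
        records.append(
            ClinicalRecord(
                patient_id=str(row["Patient_ID"]),
                survival_time=float(row["survival_time"]),
                event=bool(event),
                drugs=drugs,
            )
        )
    return records


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read the per-sample metadata TSV."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    for column in ("Patient_ID", "Tumor_Sample_Barcode"):
        if column not in frame.columns:
            raise CohortFormatError(f"{path}: missing required column {column!r}")
    metas = []
    for _, row in frame.iterrows():
        status = SampleStatus.OTHER
        if "status" in frame.columns and not pd.isna(row["status"]):
            try:
                status = SampleStatus(str(row["status"]))
            except ValueError:
                status = SampleStatus.OTHER

        def opt(column: str) -> float | None:
            if column not in frame.columns or pd.isna(row[column]):
                return None
            return float(row[column])

        metas.append(
            SampleMeta(
                patient_id=str(row["Patient_ID"]),
                sample_id=str(row["Tumor_Sample_Barcode"]),
                status=status,
                timepoint=opt("timepoint"),
                tumor_purity=opt("tumor_purity"),
                msi_score=opt("msi_score"),
                cna_fraction=opt("cna_fraction"),
            )
        )
    return metas


def order_samples(
    metas: Sequence[SampleMeta],
    mutation_counts: Mapping[str, int] | None = None,
) -> list[SampleMeta]:
    """Order one patient's samples from earliest to latest.

    Samples are ordered by ``timepoint`` when recorded.  When timepoints are
    missing or tied, an earlier sample is assumed to carry fewer mutations,
    so ties break by ascending total mutation count; residual ties break
    lexicographically by sample id, making the order total and deterministic.
    """
    counts = mutation_counts or {}

    def key(meta: SampleMeta) -> tuple:
        timepoint = meta.timepoint if meta.timepoint is not None else math.inf
        return (timepoint, counts.get(meta.sample_id, 0), meta.sample_id)

    return sorted(metas, key=key)


#: Genomes scoring strictly above this microsatellite-instability score are
#: classified as unstable.
MSI_THRESHOLD = 3.5


def msi_classify(msi_score: float) -> str:
    """Classify a microsatellite-instability score into ``"MSI"``/``"MSS"``.

    The boundary is strict: a score of exactly 3.5 is stable.
    """
    if msi_score < 0:
        raise CohortValidationError(f"MSI score must be non-negative, got {msi_score}")
    return "MSI" if msi_score > MSI_THRESHOLD else "MSS"
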