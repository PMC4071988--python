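"""Reading, writing and validating per-study genotype-count tables.

The interchange format is a flat CSV with one study per row:

    study_id,year,case_11,case_12,case_22,ctrl_11,ctrl_12,ctrl_22

plus optional metadata columns (``case_source``, ``control_source``,
``specimen``, ``hwe_in_controls``, ``total_sample_size``) used by the
quality rubric.  Lines starting with ``#`` are comments.  Three bundled
datasets ship with the package: the genotype tables of the published
XRCC3 ovarian-cancer case-control studies (SNPs rs861539, rs1799794 and
rs1799796), with study characteristics from the source articles.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import SchemaError, UnknownFixtureError, ValidationError
from .types import (
    CaseSource,
    ControlSource,
    GenotypeCounts,
    QualityFeatures,
    SNPDataset,
    Specimen,
    StudyRecord,
)

__all__ = [
    "read_study_table",
    "write_study_table",
    "load_fixture",
    "load_study_characteristics",
    "validate_dataset",
    "Finding",
    "FIXTURE_SNPS",
]

FIXTURE_SNPS = ("rs861539", "rs1799794", "rs1799796")

_COUNT_COLUMNS = ("case_11", "case_12", "case_22", "ctrl_11", "ctrl_12", "ctrl_22")
_REQUIRED_COLUMNS = ("study_id", "year") + _COUNT_COLUMNS
_METADATA_COLUMNS = (
    "case_source",
    "control_source",
    "specimen",
    "hwe_in_controls",
    "total_sample_size",
)

# Accepted tokens for the metadata enums (case-insensitive; spaces and
# hyphens normalise to underscores).
_CASE_SOURCE_TOKENS = {
    "population": CaseSource.POPULATION_OR_REGISTRY,
    "registry": CaseSource.POPULATION_OR_REGISTRY,
    "cancer_registry": CaseSource.POPULATION_OR_REGISTRY,
    "population_or_registry": CaseSource.POPULATION_OR_REGISTRY,
    "mixed": CaseSource.MIXED,
    "hospital": CaseSource.HOSPITAL,
    "other": CaseSource.OTHER,
}
_CONTROL_SOURCE_TOKENS = {
    "population": ControlSource.POPULATION,
    "population_based": ControlSource.POPULATION,
    "volunteers": ControlSource.VOLUNTEERS_OR_BLOOD_BANK,
    "blood_bank": ControlSource.VOLUNTEERS_OR_BLOOD_BANK,
    "volunteers_or_blood_bank": ControlSource.VOLUNTEERS_OR_BLOOD_BANK,
    "hospital": ControlSource.HOSPITAL_CANCER_FREE,
    "cancer_free": ControlSource.HOSPITAL_CANCER_FREE,
    "hospital_cancer_free": ControlSource.HOSPITAL_CANCER_FREE,
    "not_described": ControlSource.NOT_DESCRIBED,
}
_SPECIMEN_TOKENS = {
    "blood": Specimen.BLOOD_OR_NORMAL_TISSUE,
    "normal_tissue": Specimen.BLOOD_OR_NORMAL_TISSUE,
    "blood_or_normal_tissue": Specimen.BLOOD_OR_NORMAL_TISSUE,
    "mixed": Specimen.MIXED_BLOOD_PARAFFIN,
    "mixed_blood_paraffin": Specimen.MIXED_BLOOD_PARAFFIN,
    "tumor": Specimen.TUMOR_OR_EXFOLIATED,
    "exfoliated": Specimen.TUMOR_OR_EXFOLIATED,
    "tumor_or_exfoliated": Specimen.TUMOR_OR_EXFOLIATED,
}
_BOOL_TOKENS = {
    "yes": True, "no": False, "true": True, "false": False, "1": True, "0": False,
}


def _norm_token(value: str) -> str:
    return str(value).strip().lower().replace("-", "_").replace(" ", "_")


def _parse_enum(value, tokens: dict, field: str, row: int):
    key = _norm_token(value)
    if key not in tokens:
        raise ValidationError(
            f"row {row}: unrecognised {field} {value!r}; "
            f"expected one of {sorted(set(tokens))}"
        )
    return tokens[key]


def _parse_count(value, column: str, row: int) -> int:
    text = str(value).strip()
    try:
        number = float(text)
    except ValueError:
        raise ValidationError(f"row {row}: column {column} is not a number: {value!r}")
    if number != int(number):
        raise ValidationError(f"row {row}: column {column} must be an integer, got {value!r}")
    n = int(number)
    if n < 0:
        raise ValidationError(f"row {row}: column {column} is negative ({n})")
    return n


def _row_metadata(row: pd.Series, row_no: int) -> QualityFeatures | None:
    present = [c for c in _METADATA_COLUMNS if c in row.index and pd.notna(row[c])]
    if not present:
        return None
    missing = [c for c in _METADATA_COLUMNS if c not in present]
    if missing:
        raise ValidationError(
            f"row {row_no}: partial study metadata; missing {missing}"
        )
    return QualityFeatures(
        case_source=_parse_enum(row["case_source"], _CASE_SOURCE_TOKENS, "case_source", row_no),
        control_source=_parse_enum(
            row["control_source"], _CONTROL_SOURCE_TOKENS, "control_source", row_no
        ),
        specimen=_parse_enum(row["specimen"], _SPECIMEN_TOKENS, "specimen", row_no),
        hwe_in_controls=_parse_enum(
            row["hwe_in_controls"], _BOOL_TOKENS, "hwe_in_controls", row_no
        ),
        total_sample_size=_parse_count(row["total_sample_size"], "total_sample_size", row_no),
    )


def read_study_table(path, snp_id: str, sep: str = ",") -> SNPDataset:
    """Read a per-study genotype-count CSV into an :class:`SNPDataset`.

    ``sep='\\t'`` accepts tab-separated tables.  Raises :class:`SchemaError`
    for missing columns and :class:`ValidationError` for bad values (the
    message cites the 1-based data-row number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, skip_blank_lines=True)
    return _dataset_from_frame(df, snp_id)


def _dataset_from_frame(df: pd.DataFrame, snp_id: str) -> SNPDataset:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    studies, seen = [], set()
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        study_id = str(row["study_id"]).strip()
        if study_id in seen:
            raise ValidationError(f"row {i}: duplicate study_id {study_id!r}")
        seen.add(study_id)
        counts = {c: _parse_count(row[c], c, i) for c in _COUNT_COLUMNS}
        studies.append(
            StudyRecord(
                study_id=study_id,
                year=_parse_count(row["year"], "year", i),
                cases=GenotypeCounts(counts["case_11"], counts["case_12"], counts["case_22"]),
                controls=GenotypeCounts(counts["ctrl_11"], counts["ctrl_12"], counts["ctrl_22"]),
                metadata=_row_metadata(row, i),
            )
        )
    return SNPDataset(snp_id, studies)


def write_study_table(ds: SNPDataset, path, sep: str = ",", header_comment: str | None = None) -> None:
    """Write a dataset back to the CSV schema (numeric round-trip exact)."""
    rows = []
    with_meta = any(s.metadata is not None for s in ds.studies)
    for s in ds.studies:
        row = {
            "study_id": s.study_id,
            "year": s.year,
            "case_11": s.cases.n11, "case_12": s.cases.n12, "case_22": s.cases.n22,
            "ctrl_11": s.controls.n11, "ctrl_12": s.controls.n12, "ctrl_22": s.controls.n22,
        }
        if with_meta:
            m = s.metadata
            row.update(
                case_source=m.case_source.value if m else None,
                control_source=m.control_source.value if m else None,
                specimen=m.specimen.value if m else None,
                hwe_in_controls={True: "yes", False: "no"}.get(m.hwe_in_controls) if m else None,
                total_sample_size=m.total_sample_size if m else None,
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep=sep, index=False)


def load_fixture(snp_id: str) -> SNPDataset:
    """Load one of the bundled published genotype tables by SNP id."""
    if snp_id not in FIXTURE_SNPS:
        raise UnknownFixtureError(
            f"unknown bundled SNP {snp_id!r}; available: {', '.join(FIXTURE_SNPS)}"
        )
    ref = resources.files("genemeta.data").joinpath(f"{snp_id}.csv")
    with resources.as_file(ref) as path:
        return read_study_table(path, snp_id)


def load_study_characteristics() -> pd.DataFrame:
    """Article-level characteristics of the bundled studies.

    One row per source article: design descriptors, total cases/controls
    enrolled, and the quality score reported by the original reviewers
    (``reported_quality``) for comparison with :func:`quality_score`.
    """
    ref = resources.files("genemeta.data").joinpath("study_characteristics.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


@dataclass(frozen=True)
class Finding:
    """One dataset-validation finding; severity is 'error' or 'info'."""

    study_id: str | None
    field: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:
        who = self.study_id or "<dataset>"
        return f"[{self.severity}] {who}.{self.field}: {self.message}"


def validate_dataset(ds: SNPDataset, include_info: bool = False) -> list[Finding]:
    """Check dataset invariants, returning findings instead of raising.

    Errors: no studies, duplicate ids, an empty arm.  Info findings (off by
    default) flag a metadata sample size that disagrees with the genotype-row
    total — expected when a source article genotyped only a subset at this
    SNP — without altering either number.
    """
    findings: list[Finding] = []
    if ds.k == 0:
        findings.append(Finding(None, "studies", "no studies in dataset"))
        return findings
    seen: set[str] = set()
    for s in ds.studies:
        if s.study_id in seen:
            findings.append(Finding(s.study_id, "study_id", "duplicate study_id"))
        seen.add(s.study_id)
        for arm_name, arm in (("cases", s.cases), ("controls", s.controls)):
            if arm.total < 1:
                findings.append(Finding(s.study_id, arm_name, "empty arm (all counts zero)"))
        if include_info and s.metadata is not None:
            genotyped = s.cases.total + s.controls.total
            if s.metadata.total_sample_size != genotyped:
                findings.append(
                    Finding(
                        s.study_id,
                        "total_sample_size",
                        f"metadata total {s.metadata.total_sample_size} differs from "
                        f"genotype-row total {genotyped}",
                        severity="info",
                    )
                )
    return findings
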