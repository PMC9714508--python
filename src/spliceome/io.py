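"""Reading, validation and harmonization of the pipeline's tabular inputs.

The in-memory model is deliberately plain pandas:

* expression — ``DataFrame`` of non-negative TPM, rows indexed by
  ``transcript_id``, columns are sample ids;
* annotation — ``DataFrame`` indexed by ``transcript_id`` with columns
  ``gene_id``, ``gene_symbol``, ``biotype``, ``protein_length_aa``;
* samples — ``DataFrame`` indexed by ``sample_id`` with the grouping
  factors (subject, tissue, sex, age bracket, library prep, project,
  condition), with missing factors filled by the ``"unknown"`` sentinel;
* genotypes — long ``DataFrame`` with ``subject_id``, ``variant_id``,
  ``dosage`` (0/1/2, nullable).

Two expression dialects are supported: GCT 1.2 (the format GTEx ships
transcript TPM in) and a plain TSV with a ``transcript_id`` leading column.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DimensionMismatchError,
    DuplicateIdError,
    EmptyTableError,
    GctFormatError,
    MissingColumnError,
    NegativeValueError,
    NonNumericValueError,
    NoOverlapError,
)

logger = logging.getLogger("spliceome")

#: Transcript biotype classes recognised by the pipeline. Anything else read
#: from an annotation buckets into ``other`` so composition always closes.
BIOTYPES = (
    "protein_coding",
    "nonsense_mediated_decay",
    "retained_intron",
    "processed_transcript",
    "lncRNA",
    "processed_pseudogene",
    "other",
)

ANNOTATION_COLUMNS = (
    "transcript_id",
    "gene_id",
    "gene_symbol",
    "biotype",
    "protein_length_aa",
)

SAMPLE_COLUMNS = (
    "sample_id",
    "subject_id",
    "tissue",
    "sex",
    "age_bracket",
    "library_prep",
    "project_id",
    "condition",
)

GENOTYPE_COLUMNS = ("subject_id", "variant_id", "dosage")

_VERSION_RE = re.compile(r"\.\d+$")
_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def coerce_biotype(value: object) -> str:
    """Map an annotation biotype string onto the recognised classes.

    Unknown strings (``TEC``, ``lincRNA`` variants the enum lacks, ...)
    map to ``other``; ``lncRNA`` is matched case-insensitively.
    """
    s = str(value).strip()
    if s in BIOTYPES:
        return s
    if s.lower() == "lncrna":
        return "lncRNA"
    return "other"


def strip_version(transcript_id: str) -> str:
    """Drop a trailing ``.<digits>`` version suffix (ENST00000001.4 → ENST00000001)."""
    return _VERSION_RE.sub("", transcript_id)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _validate_expression(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateIdError(f"{source}: duplicate transcript id(s) {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise DuplicateIdError(f"{source}: duplicate sample id(s) {dups[:5]}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise NonNumericValueError(f"{source}: non-numeric expression value ({exc})")
    arr = values.to_numpy()
    if not np.all(np.isfinite(arr)):
        raise NonNumericValueError(f"{source}: non-finite expression value")
    if (arr < 0).any():
        raise NegativeValueError(f"{source}: negative expression value")
    values.index = values.index.astype(str)
    values.index.name = "transcript_id"
    values.columns = values.columns.astype(str)
    return values


def read_expression(path, format: str = "gct") -> pd.DataFrame:
    """Read a transcript × sample TPM matrix from a GCT 1.2 or TSV file."""
    if format == "gct":
        return _read_gct(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if df.shape[1] < 2 or df.columns[0] != "transcript_id":
            raise MissingColumnError(f"{path}: TSV expression must start with 'transcript_id'")
        df = df.set_index("transcript_id")
        return _validate_expression(df, str(path))
    raise ValueError(f"unknown expression format {format!r}")


def _read_gct(path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().rstrip("\n")
        if version != "#1.2":
            raise GctFormatError(f"{path}: expected '#1.2' version line, got {version!r}")
        dims = fh.readline().rstrip("\n").split("\t")
        if len(dims) < 2:
            raise GctFormatError(f"{path}: malformed dimension line")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError:
            raise GctFormatError(f"{path}: non-integer dimension line {dims!r}")
        df = pd.read_csv(fh, sep="\t", dtype={0: str, 1: str})
    if df.columns[0] != "Name" or df.columns[1] != "Description":
        raise GctFormatError(f"{path}: header must start with 'Name\\tDescription'")
    if df.shape[0] != n_rows or df.shape[1] - 2 != n_cols:
        raise DimensionMismatchError(
            f"{path}: dimension line says {n_rows}x{n_cols}, "
            f"data block is {df.shape[0]}x{df.shape[1] - 2}"
        )
    df = df.drop(columns="Description").set_index("Name")
    return _validate_expression(df, str(path))


def write_expression(matrix: pd.DataFrame, path, format: str = "gct") -> None:
    """Write a TPM matrix in the dialects ``read_expression`` accepts."""
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(matrix.columns) + "\n")
            for tx, row in matrix.iterrows():
                fh.write(tx + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif format == "tsv":
        out = matrix.copy()
        out.index.name = "transcript_id"
        out.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def read_annotation(path, format: str = "tsv") -> pd.DataFrame:
    """Read a transcript annotation (TSV dialect or GTF transcript lines).

    Returns a DataFrame indexed by ``transcript_id``. Unknown biotype
    strings map to ``other``; duplicate transcript rows are dropped
    first-wins with a logged warning.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns and c != "protein_length_aa"]
        if missing:
            raise MissingColumnError(f"{path}: annotation TSV missing column(s) {missing}")
        if "protein_length_aa" not in df.columns:
            df["protein_length_aa"] = np.nan
    elif format == "gtf":
        df = _read_gtf_transcripts(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if df.empty:
        raise EmptyTableError(f"{path}: annotation table is empty")
    if df["transcript_id"].duplicated().any():
        n = int(df["transcript_id"].duplicated().sum())
        logger.warning("%s: %d duplicate transcript row(s) dropped (first wins)", path, n)
        df = df.drop_duplicates(subset="transcript_id", keep="first")
    df = df.copy()
    df["biotype"] = df["biotype"].map(coerce_biotype)
    df["protein_length_aa"] = pd.to_numeric(df["protein_length_aa"], errors="coerce")
    # protein length only meaningful for (potentially) translated classes
    coding = df["biotype"].isin(["protein_coding", "nonsense_mediated_decay"])
    df.loc[~coding, "protein_length_aa"] = np.nan
    return df.set_index("transcript_id")[["gene_id", "gene_symbol", "biotype", "protein_length_aa"]]


def _read_gtf_transcripts(path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "transcript":
                continue
            attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise MissingColumnError(
                    f"{path}: GTF transcript line lacks transcript_id/gene_id"
                )
            biotype = attrs.get("transcript_type") or attrs.get("transcript_biotype") or "other"
            records.append(
                {
                    "transcript_id": attrs["transcript_id"],
                    "gene_id": attrs["gene_id"],
                    "gene_symbol": attrs.get("gene_name", attrs["gene_id"]),
                    "biotype": biotype,
                    "protein_length_aa": np.nan,
                }
            )
    return pd.DataFrame(records, columns=list(ANNOTATION_COLUMNS))


def gene_index(annotation: pd.DataFrame) -> dict[str, list[str]]:
    """gene_id → ordered list of member transcript ids."""
    return {g: list(sub.index) for g, sub in annotation.groupby("gene_id", sort=False)}


# ---------------------------------------------------------------------------
# sample metadata and genotypes
# ---------------------------------------------------------------------------


def read_samples(path) -> pd.DataFrame:
    """Read the sample metadata TSV; missing factors become ``"unknown"``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise MissingColumnError(f"{path}: sample table missing 'sample_id'")
    for col in SAMPLE_COLUMNS:
        if col not in df.columns:
            df[col] = "unknown"
    df = df[list(SAMPLE_COLUMNS)].fillna("unknown").replace("", "unknown")
    if df["sample_id"].duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate sample id(s)")
    return df.set_index("sample_id")


def read_genotypes(path) -> pd.DataFrame:
    """Read a long genotype dosage table (subject_id, variant_id, dosage)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "variant_id": str})
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: genotype table missing column(s) {missing}")
    df = df[list(GENOTYPE_COLUMNS)].copy()
    df["dosage"] = pd.to_numeric(df["dosage"], errors="coerce")
    bad = df["dosage"].dropna()
    if not bad.isin([0, 1, 2]).all():
        raise NonNumericValueError(f"{path}: dosage values must be 0, 1 or 2")
    df["dosage"] = df["dosage"].astype("Int64")
    if df.duplicated(subset=["subject_id", "variant_id"]).any():
        raise DuplicateIdError(f"{path}: duplicate (subject, variant) row(s)")
    return df


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


@dataclass
class HarmonizeReport:
    """Book-keeping from matching an expression matrix against an annotation."""

    n_matrix_transcripts: int
    n_matched_transcripts: int
    n_unmatched_transcripts: int
    n_matched_genes: int
    unmatched_transcript_ids: tuple = field(default_factory=tuple)

    @property
    def unmatched_transcripts(self) -> int:  # convenience alias
        return self.n_unmatched_transcripts


def harmonize(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    strip_versions: bool = True,
    gene_symbols: set | None = None,
):
    """Restrict a TPM matrix to annotated transcripts (optionally, to a gene set).

    Version suffixes (the part after the final ``.``) are stripped from both
    sides by default, since expression providers and annotation releases
    commonly disagree on them. Returns ``(matrix, annotation, report)``;
    raises :class:`NoOverlapError` when nothing matches.
    """
    mat = matrix.copy()
    ann = annotation.copy()
    if strip_versions:
        mat.index = mat.index.map(strip_version)
        ann.index = ann.index.map(strip_version)
        if mat.index.has_duplicates or ann.index.has_duplicates:
            raise DuplicateIdError("version stripping produced duplicate transcript ids")
    if gene_symbols is not None:
        ann = ann[ann["gene_symbol"].isin(set(gene_symbols))]
    matched = mat.index.intersection(ann.index)
    if len(matched) == 0:
        raise NoOverlapError(
            "no transcripts shared between expression matrix and annotation "
            "(identifier scheme mismatch?)"
        )
    kept = mat.loc[mat.index.isin(matched)]
    ann_kept = ann.loc[ann.index.isin(matched)]
    unmatched = tuple(mat.index[~mat.index.isin(matched)])
    report = HarmonizeReport(
        n_matrix_transcripts=mat.shape[0],
        n_matched_transcripts=len(matched),
        n_unmatched_transcripts=len(unmatched),
        n_matched_genes=ann_kept["gene_id"].nunique(),
        unmatched_transcript_ids=unmatched,
    )
    return kept, ann_kept, report
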