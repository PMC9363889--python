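"""Reading and writing AIRR-style rearrangement tables and sample manifests.

Rearrangement input follows the AIRR Rearrangement TSV convention
(tab-separated, UTF-8, header row). Column names are resolved through a
*dialect* mapping from the canonical field names used throughout this
package (``sample_id``, ``umi``, ``cdr3_nt``, ``v_gene``, ``j_gene``,
``cdr3_aa``, ``duplicate_count``) to whatever the file calls them; the
default dialect uses the AIRR community names (``cdr3``, ``v_call``,
``j_call``, ``duplicate_count``).

Validation is total: every input row either becomes a validated record or
is listed, with a reason, in the rejection report returned alongside the
records. Nothing is silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "JOINTS",
    "DEFAULT_DIALECT",
    "RECORD_COLUMNS",
    "RearrangementRecord",
    "SampleMeta",
    "ReadReport",
    "normalize_gene_call",
    "read_rearrangements",
    "read_manifest",
    "write_table",
    "records_to_frame",
]

#: Accepted compartment labels: synovial-tissue suprapatellar / infrapatellar
#: biopsy sites, synovial fluid, peripheral blood.
COMPARTMENTS = ("ST_SP", "ST_IP", "SF", "PB")

#: Accepted joint labels; "other" is used for non-joint samples (blood).
JOINTS = ("left_knee", "right_knee", "ankle", "other")

#: Canonical field name -> AIRR Rearrangement TSV column name.
DEFAULT_DIALECT: dict[str, str] = {
    "sample_id": "sample_id",
    "umi": "umi",
    "cdr3_nt": "cdr3",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "cdr3_aa": "cdr3_aa",
    "duplicate_count": "duplicate_count",
}

#: Column order of the canonical in-memory record frame.
RECORD_COLUMNS = (
    "sample_id",
    "umi",
    "cdr3_nt",
    "v_gene",
    "j_gene",
    "cdr3_aa",
    "duplicate_count",
)

_MANDATORY = ("umi", "cdr3_nt", "v_gene", "j_gene")
_CDR3_RE = re.compile(r"^[ACGTN]+$")
_UMI_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class RearrangementRecord:
    """One annotated sequencing molecule (or read) of a BCR heavy chain.

    ``duplicate_count`` is the number of raw reads carrying this UMI
    (>= 1); after UMI collapsing one record represents one molecule.
    """

    sample_id: str
    umi: str
    cdr3_nt: str
    v_gene: str
    j_gene: str
    cdr3_aa: str | None = None
    duplicate_count: int = 1

    def __post_init__(self) -> None:
        if not self.cdr3_nt or not _CDR3_RE.match(self.cdr3_nt):
            raise ValueError(
                f"cdr3_nt must be non-empty over alphabet ACGTN, got {self.cdr3_nt!r}"
            )
        if not self.umi:
            raise ValueError("umi must be non-empty")
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level metadata: which patient, joint and compartment."""

    sample_id: str
    patient_id: str
    joint: str
    compartment: str
    collection_day: int = 0

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; accepted: {COMPARTMENTS}"
            )
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}; accepted: {JOINTS}")
        if self.compartment in ("ST_SP", "ST_IP", "SF") and self.joint == "other":
            raise ValueError(
                f"sample {self.sample_id}: tissue/fluid compartment "
                f"{self.compartment} requires a joint"
            )
        if self.compartment == "PB" and self.joint != "other":
            raise ValueError(
                f"sample {self.sample_id}: PB requires joint='other'"
            )


@dataclass
class ReadReport:
    """Per-file validation accounting; rejected + accepted == total rows."""

    path: str
    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def normalize_gene_call(call: str) -> str:
    """Strip an IMGT allele suffix: ``IGHV3-23*01`` -> ``IGHV3-23``."""
    return call.split("*", 1)[0]


def records_to_frame(records: Sequence[RearrangementRecord]) -> pd.DataFrame:
    """Canonical DataFrame form of a record list (stable column order)."""
    return pd.DataFrame(
        [
            (r.sample_id, r.umi, r.cdr3_nt, r.v_gene, r.j_gene, r.cdr3_aa, r.duplicate_count)
            for r in records
        ],
        columns=list(RECORD_COLUMNS),
    )


def read_rearrangements(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    sample_id: str | None = None,
    strip_alleles: bool = True,
    drop_n_cdr3: bool = False,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read one AIRR rearrangement TSV into a validated record frame.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    dialect
        Mapping of canonical field names to this file's column names;
        defaults to :data:`DEFAULT_DIALECT`. ``cdr3_aa``,
        ``duplicate_count`` and ``sample_id`` are optional in the file
        (``sample_id`` may instead be supplied via the argument).
    sample_id
        Overrides / supplies the sample identifier when the file has no
        sample_id column.
    strip_alleles
        Normalize gene calls to gene level by dropping ``*allele``.
    drop_n_cdr3
        Reject records whose CDR3 contains N (kept by default).

    Returns
    -------
    (records, report)
        ``records`` is a DataFrame in :data:`RECORD_COLUMNS` order;
        ``report`` lists every rejected row index and the reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty and raw.columns.empty:
        raise ValueError(f"{path}: empty file")

    for fieldname in _MANDATORY:
        col = dialect[fieldname]
        if col not in raw.columns:
            raise ValueError(
                f"{path}: missing mandatory column {col!r} (field {fieldname!r})"
            )

    report = ReadReport(path=str(path), n_rows=len(raw))
    out = pd.DataFrame(index=raw.index)
    out["umi"] = raw[dialect["umi"]].str.upper()
    out["cdr3_nt"] = raw[dialect["cdr3_nt"]].str.upper()
    out["v_gene"] = raw[dialect["v_gene"]]
    out["j_gene"] = raw[dialect["j_gene"]]

    sid_col = dialect["sample_id"]
    if sample_id is not None:
        out["sample_id"] = sample_id
    elif sid_col in raw.columns:
        out["sample_id"] = raw[sid_col]
    else:
        raise ValueError(
            f"{path}: no {sid_col!r} column and no sample_id argument given"
        )

    aa_col = dialect["cdr3_aa"]
    out["cdr3_aa"] = raw[aa_col].str.upper() if aa_col in raw.columns else None

    dup_col = dialect["duplicate_count"]
    if dup_col in raw.columns:
        dup = pd.to_numeric(raw[dup_col], errors="coerce")
    else:
        dup = pd.Series(1, index=raw.index, dtype=float)
    out["duplicate_count"] = dup

    if strip_alleles:
        out["v_gene"] = out["v_gene"].str.split("*").str[0]
        out["j_gene"] = out["j_gene"].str.split("*").str[0]

    cdr3_pat = r"^[ACGT]+$" if drop_n_cdr3 else r"^[ACGTN]+$"
    bad_cdr3 = ~out["cdr3_nt"].str.match(cdr3_pat)
    bad_umi = ~out["umi"].str.match(_UMI_RE)
    bad_gene = (out["v_gene"].str.len() == 0) | (out["j_gene"].str.len() == 0)
    bad_dup = dup.isna() | (dup < 1)
    for idx in raw.index:
        if bad_cdr3.iat[idx]:
            report.rejected.append((int(idx), "invalid cdr3_nt"))
        elif bad_umi.iat[idx]:
            report.rejected.append((int(idx), "invalid umi"))
        elif bad_gene.iat[idx]:
            report.rejected.append((int(idx), "empty gene call"))
        elif bad_dup.iat[idx]:
            report.rejected.append((int(idx), "duplicate_count < 1 or non-numeric"))

    keep = ~(bad_cdr3 | bad_umi | bad_gene | bad_dup)
    records = out.loc[keep, list(RECORD_COLUMNS)].reset_index(drop=True)
    records["duplicate_count"] = records["duplicate_count"].astype(int)
    report.n_accepted = len(records)
    return records, report


def read_manifest(path: str | Path) -> list[SampleMeta]:
    """Read the sample manifest CSV.

    Expected columns: sample_id, patient_id, joint, compartment,
    collection_day (optional, default 0). Duplicate sample_ids and
    unknown compartment/joint labels are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "patient_id", "joint", "compartment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample_id(s): {sorted(set(dupes))}")
    metas = []
    for _, row in df.iterrows():
        day = int(row["collection_day"]) if row.get("collection_day", "") != "" else 0
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                joint=row["joint"],
                compartment=row["compartment"],
                collection_day=day,
            )
        )
    return metas


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    *,
    allow_empty: bool = False,
    sep: str = "\t",
    float_precision: int = 10,
) -> None:
    """Write a result table as delimited text, deterministically.

    Floats are serialized with a fixed number of significant digits
    (default 10) so repeated runs produce byte-identical files; the
    written file re-reads to the same values.
    """
    if table.empty and not allow_empty:
        raise ValueError(f"refusing to write empty table to {path} (allow_empty=False)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=sep, index=False, float_format=f"%.{float_precision}g")
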