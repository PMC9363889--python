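"""Clonotype calling: UMI collapsing and clone aggregation.

A clone (clonotype) is the set of molecules sharing one *clone key*:
the CDR3 nucleotide (or amino-acid) sequence together with the V and J
gene calls. Quantification is molecule-based: PCR duplicates sharing a
UMI collapse to a single molecule first, and clone frequencies are
molecule shares of the sample. For cross-sample similarity analysis the
key is projected down to the CDR3 sequence alone, because somatic
hypermutation makes V/J-resolved keys overly fragmented across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_airr import RECORD_COLUMNS, RearrangementRecord, SampleMeta, records_to_frame

__all__ = ["CloneKey", "Repertoire", "collapse_umis", "build_repertoire", "project_to_cdr3"]

#: Columns of a repertoire clone table.
CLONE_COLUMNS = ("cdr3", "v_gene", "j_gene", "molecule_count", "frequency")


@dataclass(frozen=True)
class CloneKey:
    """Identity of a clone: CDR3 sequence plus (optionally) V and J genes.

    Within-sample keys carry ``v_gene``/``j_gene``; CDR3-projected keys
    used for cross-sample comparison leave them as ``None``.
    """

    cdr3: str
    v_gene: str | None = None
    j_gene: str | None = None


@dataclass
class Repertoire:
    """Quantified per-sample clone table.

    ``clones`` has columns ``cdr3, v_gene, j_gene, molecule_count,
    frequency``, sorted deterministically by (molecule_count desc, cdr3,
    v_gene, j_gene). Frequencies are exact molecule shares and sum to 1.
    """

    meta: SampleMeta
    clones: pd.DataFrame
    total_molecules: int

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def is_cdr3_projected(self) -> bool:
        return self.clones["v_gene"].isna().all() if len(self.clones) else True

    def validate(self) -> None:
        c = self.clones
        if list(c.columns) != list(CLONE_COLUMNS):
            raise ValueError(f"clone table columns must be {CLONE_COLUMNS}")
        if int(c["molecule_count"].sum()) != self.total_molecules:
            raise ValueError("total_molecules != sum of clone molecule counts")
        if len(c) and not np.isclose(c["frequency"].sum(), 1.0, atol=1e-9):
            raise ValueError("clone frequencies must sum to 1")
        keys = c[["cdr3", "v_gene", "j_gene"]]
        if keys.duplicated().any():
            raise ValueError("duplicate clone keys")

    def copy(self) -> "Repertoire":
        return replace(self, clones=self.clones.copy())


def _canonical_sort(clones: pd.DataFrame) -> pd.DataFrame:
    """Deterministic clone order: count desc, then CDR3, then V, then J."""
    return clones.sort_values(
        ["molecule_count", "cdr3", "v_gene", "j_gene"],
        ascending=[False, True, True, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def collapse_umis(records: Sequence[RearrangementRecord] | pd.DataFrame) -> pd.DataFrame:
    """Collapse raw reads to molecules: one row per (UMI, clone key).

    Reads sharing both UMI and clone key merge into a single molecule
    whose ``duplicate_count`` is the number of reads merged. A UMI seen
    with two different clone keys (a UMI collision) yields two distinct
    molecules; no majority vote is applied. Idempotent, and invariant to
    input row order.
    """
    df = _as_frame(records)
    if df.empty:
        raise ValueError("collapse_umis: empty input")
    if df["sample_id"].nunique() > 1:
        raise ValueError("collapse_umis: records span multiple samples")
    grouped = (
        df.groupby(
            ["sample_id", "umi", "cdr3_nt", "v_gene", "j_gene"],
            dropna=False,
            sort=True,
        )
        .agg(cdr3_aa=("cdr3_aa", "first"), duplicate_count=("duplicate_count", "sum"))
        .reset_index()
    )
    return grouped[list(RECORD_COLUMNS)]


def build_repertoire(
    molecules: Sequence[RearrangementRecord] | pd.DataFrame,
    meta: SampleMeta,
    mode: Literal["nt", "aa"] = "nt",
) -> Repertoire:
    """Aggregate UMI-collapsed molecules into a quantified Repertoire.

    Each molecule counts once (duplicate_count, the raw-read
    multiplicity behind the molecule, does not weight clone sizes).
    ``mode="aa"`` keys clones by the CDR3 amino-acid sequence instead of
    nucleotide; it requires cdr3_aa on every molecule.
    """
    df = _as_frame(molecules)
    if df.empty:
        raise ValueError("build_repertoire: empty input")
    if mode == "aa":
        if df["cdr3_aa"].isna().any() or (df["cdr3_aa"].astype(str).str.len() == 0).any():
            raise ValueError("mode='aa' requires cdr3_aa on every molecule")
        cdr3 = df["cdr3_aa"].astype(str)
    elif mode == "nt":
        cdr3 = df["cdr3_nt"]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    key = pd.DataFrame({"cdr3": cdr3, "v_gene": df["v_gene"], "j_gene": df["j_gene"]})
    counts = (
        key.groupby(["cdr3", "v_gene", "j_gene"], sort=True)
        .size()
        .rename("molecule_count")
        .reset_index()
    )
    total = int(counts["molecule_count"].sum())
    counts["frequency"] = counts["molecule_count"] / total
    clones = _canonical_sort(counts[list(CLONE_COLUMNS)])
    rep = Repertoire(meta=meta, clones=clones, total_molecules=total)
    rep.validate()
    return rep


def project_to_cdr3(r: Repertoire) -> Repertoire:
    """Merge clones sharing a CDR3 regardless of V/J (cross-sample key).

    Counts of merged clones are summed; total molecules and the
    frequency sum (=1) are conserved. Idempotent.
    """
    merged = (
        r.clones.groupby("cdr3", sort=True)["molecule_count"]
        .sum()
        .reset_index()
    )
    merged["v_gene"] = pd.NA
    merged["j_gene"] = pd.NA
    merged["frequency"] = merged["molecule_count"] / r.total_molecules
    clones = _canonical_sort(merged[list(CLONE_COLUMNS)])
    out = Repertoire(meta=r.meta, clones=clones, total_molecules=r.total_molecules)
    out.validate()
    return out
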