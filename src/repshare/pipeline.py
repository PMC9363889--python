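"""End-to-end orchestration: ingest -> clonotype -> standardize depth ->
summarize -> pairwise overlap -> group comparisons, from one config.

All randomness flows from a single master seed; outputs are plain
TSV/CSV tables plus a JSON run record (config snapshot, version,
per-output checksums, seeds, timestamps) so a run can be verified to
reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from . import __version__
from .clonotyping import build_repertoire, collapse_umis, project_to_cdr3
from .group_stats import aggregate, compare
from .io_airr import read_manifest, read_rearrangements, write_table
from .overlap import overlap_plot_data, overlaps_to_frame, pairwise_overlaps
from .repertoire_stats import (
    DEFAULT_DEPTH,
    DEFAULT_HEC_THRESHOLD,
    DepthConfig,
    subsample,
    summarize_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "analyze_records"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    manifest: str
    #: sample_id -> rearrangement TSV path; if empty, <data_dir>/<sample_id>.tsv
    rearrangement_files: dict[str, str] = field(default_factory=dict)
    data_dir: str = "."
    out_dir: str = "results"
    depth: int = DEFAULT_DEPTH
    seed: int = 0
    shallow_policy: Literal["error", "keep_all"] = "error"
    hec_threshold: float = DEFAULT_HEC_THRESHOLD
    top_n: int = 25
    mode: Literal["cdr3-nt", "cdr3-aa"] = "cdr3-nt"
    chao_variant: Literal["bias_corrected", "uncorrected"] = "bias_corrected"
    keep_going: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolve_files(self) -> dict[str, Path]:
        metas = read_manifest(self.manifest)
        files = {}
        for m in metas:
            p = Path(
                self.rearrangement_files.get(
                    m.sample_id, str(Path(self.data_dir) / f"{m.sample_id}.tsv")
                )
            )
            files[m.sample_id] = p
        return files


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run record (also written).

    Outputs in ``cfg.out_dir``: ``repertoires.tsv`` (all clone tables at
    standardized depth), ``summary.tsv``, ``overlap.tsv``,
    ``overlap_plot.tsv``, ``comparisons.tsv``, ``run_record.json``.
    """
    t0 = time.time()
    metas = read_manifest(cfg.manifest)
    files = cfg.resolve_files()
    missing = [str(p) for p in files.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"rearrangement files not found: {missing}")

    depth_cfg = DepthConfig(depth=cfg.depth, seed=cfg.seed, shallow_policy=cfg.shallow_policy)
    mode = "aa" if cfg.mode == "cdr3-aa" else "nt"

    # validate depth feasibility up front so failures name every shallow sample
    reps = []
    for m in metas:
        records, report = read_rearrangements(files[m.sample_id], sample_id=m.sample_id)
        if report.n_rejected:
            logger.warning(
                "sample %s: rejected %d/%d rows", m.sample_id, report.n_rejected, report.n_rows
            )
        molecules = collapse_umis(records)
        rep = build_repertoire(molecules, m, mode=mode)
        logger.info(
            "sample %s: %d reads -> %d molecules -> %d clones",
            m.sample_id, int(records["duplicate_count"].sum()), len(molecules), rep.n_clones,
        )
        reps.append(rep)
    if cfg.shallow_policy == "error":
        shallow = [
            f"{r.meta.sample_id} ({r.total_molecules} < {cfg.depth})"
            for r in reps
            if r.total_molecules < cfg.depth
        ]
        if shallow:
            raise ValueError(f"samples below depth {cfg.depth}: {', '.join(shallow)}")

    reps = [subsample(r, depth_cfg) for r in reps]
    projected = [project_to_cdr3(r) for r in reps]

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rep_tables = []
    for r in reps:
        t = r.clones.copy()
        t.insert(0, "sample_id", r.meta.sample_id)
        rep_tables.append(t)
    write_table(pd.concat(rep_tables, ignore_index=True), out / "repertoires.tsv")

    summary = summarize_cohort(reps, cfg.hec_threshold)
    write_table(summary, out / "summary.tsv")

    results = pairwise_overlaps(projected, n_top=cfg.top_n, variant=cfg.chao_variant)
    write_table(overlaps_to_frame(results), out / "overlap.tsv", allow_empty=True)

    by_sid = {r.meta.sample_id: r for r in projected}
    plot_tables = []
    for r in results:
        t = overlap_plot_data(
            by_sid[r.sample_a], by_sid[r.sample_b], hec_threshold=cfg.hec_threshold
        )
        t.insert(0, "sample_a", r.sample_a)
        t.insert(1, "sample_b", r.sample_b)
        plot_tables.append(t)
    if plot_tables:
        write_table(pd.concat(plot_tables, ignore_index=True), out / "overlap_plot.tsv")

    comparisons = _class_comparisons(overlaps_to_frame(results))
    write_table(comparisons, out / "comparisons.tsv", allow_empty=True)

    record = {
        "version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "n_samples": len(reps),
        "n_pairs": len(results),
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": {
            p.name: _checksum(p)
            for p in sorted(out.glob("*.tsv"))
        },
    }
    (out / "run_record.json").write_text(json.dumps(record, indent=2, sort_keys=True))
    return record


def analyze_records(
    records_by_sample: dict[str, pd.DataFrame],
    manifest,
    depth_cfg: DepthConfig,
    *,
    hec_threshold: float = DEFAULT_HEC_THRESHOLD,
    top_n: int = 25,
    chao_variant: str = "bias_corrected",
):
    """In-memory analysis of already-loaded record frames.

    Runs clonotyping, depth standardization, summaries and pairwise
    overlaps without touching the filesystem; returns
    (summary table, overlap results, overlap table).
    """
    reps = [
        subsample(
            build_repertoire(collapse_umis(records_by_sample[m.sample_id]), m),
            depth_cfg,
        )
        for m in manifest
    ]
    summary = summarize_cohort(reps, hec_threshold)
    projected = [project_to_cdr3(r) for r in reps]
    results = pairwise_overlaps(projected, n_top=top_n, variant=chao_variant)
    return summary, results, overlaps_to_frame(results)


def _class_comparisons(overlap_table: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean/SD plus pairwise tests between comparison classes.

    Classes with fewer than 2 pairs are aggregated but not tested.
    Tests are unpaired two-sided Mann-Whitney U between classes on both
    overlap metrics (pairing structures across heterogeneous classes
    are not generally alignable).
    """
    if overlap_table.empty:
        return pd.DataFrame(
            columns=["metric", "group_a", "group_b", "test", "n_a", "n_b",
                     "mean_a", "sd_a", "mean_b", "sd_b", "statistic", "p_value", "significant"]
        )
    rows = []
    for metric in ("topn_retrieval_pct", "chao_sorensen"):
        agg = aggregate(overlap_table, metric, "comparison_class")
        classes = agg["comparison_class"].tolist()
        for i, ga in enumerate(classes):
            for gb in classes[i + 1:]:
                va = overlap_table.loc[overlap_table["comparison_class"] == ga, metric]
                vb = overlap_table.loc[overlap_table["comparison_class"] == gb, metric]
                if len(va) < 2 or len(vb) < 2:
                    continue
                c = compare(
                    va, vb, "mann_whitney_u", metric=metric, group_a=ga, group_b=gb
                )
                rows.append(
                    {
                        "metric": metric,
                        "group_a": ga,
                        "group_b": gb,
                        "test": c.test,
                        "n_a": c.n_a,
                        "n_b": c.n_b,
                        "mean_a": c.mean_a,
                        "sd_a": c.sd_a,
                        "mean_b": c.mean_b,
                        "sd_b": c.sd_b,
                        "statistic": c.statistic,
                        "p_value": c.p_value,
                        "significant": c.significant,
                    }
                )
    return pd.DataFrame(rows)
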