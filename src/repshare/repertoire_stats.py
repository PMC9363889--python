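"""Depth standardization and per-sample repertoire summaries.

Sequencing depth differs between samples, and both clone richness and
overlap statistics are depth-dependent, so every repertoire is reduced
to a common number of molecules before any statistic is computed. The
draw is uniform without replacement over the sample's molecules, i.e.
clone counts follow a multivariate hypergeometric distribution. The
default depth is 9,736 molecules.

A clone whose post-standardization frequency is at least 0.5% of the
repertoire is a highly expanded clone (HEC); *HEC impact* is the summed
frequency of a sample's HECs, as a percentage. At the default depth the
0.5% rule corresponds to a floor of ceil(0.005 * 9736) = 49 molecules.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .clonotyping import CLONE_COLUMNS, Repertoire, _canonical_sort

__all__ = [
    "DEFAULT_DEPTH",
    "DEFAULT_HEC_THRESHOLD",
    "DepthConfig",
    "RepertoireSummary",
    "derive_seed",
    "subsample",
    "detect_hecs",
    "summarize",
    "summarize_cohort",
]

DEFAULT_DEPTH = 9_736
DEFAULT_HEC_THRESHOLD = 0.005


@dataclass(frozen=True)
class DepthConfig:
    """Depth-standardization settings.

    ``seed`` is the master seed; each sample's draw is seeded from
    (seed, sample_id) so adding or removing samples never perturbs the
    draws of the others. ``shallow_policy`` controls samples with fewer
    molecules than ``depth``: ``"error"`` (default) aborts, naming the
    shortfall; ``"keep_all"`` keeps the sample at its native depth.
    """

    depth: int = DEFAULT_DEPTH
    seed: int = 0
    shallow_policy: Literal["error", "keep_all"] = "error"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.shallow_policy not in ("error", "keep_all"):
            raise ValueError(f"unknown shallow_policy {self.shallow_policy!r}")


@dataclass(frozen=True)
class RepertoireSummary:
    """Per-sample richness and expansion summary at a fixed depth."""

    sample_id: str
    n_clones: int
    n_hecs: int
    hec_impact: float  # percentage of the repertoire held by HECs
    depth: int


def derive_seed(master_seed: int, sample_id: str) -> int:
    """Deterministic per-sample seed from the master seed and sample id."""
    digest = hashlib.sha256(f"{master_seed}:{sample_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def subsample(r: Repertoire, cfg: DepthConfig) -> Repertoire:
    """Draw exactly ``cfg.depth`` molecules uniformly without replacement.

    Clone counts in the result are multivariate hypergeometric; clones
    drawn zero times are removed and frequencies recomputed over the new
    depth. Reproducible under a fixed (seed, sample_id).
    """
    total = r.total_molecules
    if total < cfg.depth:
        if cfg.shallow_policy == "error":
            raise ValueError(
                f"sample {r.meta.sample_id}: {total} molecules < depth "
                f"{cfg.depth} (short by {cfg.depth - total}); "
                "use shallow_policy='keep_all' to keep it at native depth"
            )
        return r.copy()
    if total == cfg.depth:
        return r.copy()
    rng = np.random.default_rng(derive_seed(cfg.seed, r.meta.sample_id))
    counts = r.clones["molecule_count"].to_numpy()
    drawn = rng.multivariate_hypergeometric(counts, cfg.depth)
    clones = r.clones.copy()
    clones["molecule_count"] = drawn
    clones = clones[clones["molecule_count"] > 0]
    clones["frequency"] = clones["molecule_count"] / cfg.depth
    clones = _canonical_sort(clones[list(CLONE_COLUMNS)])
    out = Repertoire(meta=r.meta, clones=clones, total_molecules=cfg.depth)
    out.validate()
    return out


def detect_hecs(r: Repertoire, threshold: float = DEFAULT_HEC_THRESHOLD) -> pd.DataFrame:
    """Return the clones with frequency >= threshold, in rank order.

    The boundary is inclusive: a clone at exactly the threshold is a
    HEC. The default threshold is 0.5%.
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return r.clones[r.clones["frequency"] >= threshold].reset_index(drop=True)


def summarize(r: Repertoire, threshold: float = DEFAULT_HEC_THRESHOLD) -> RepertoireSummary:
    """Clone count, HEC count and HEC impact (%) for one sample."""
    hecs = detect_hecs(r, threshold)
    return RepertoireSummary(
        sample_id=r.meta.sample_id,
        n_clones=r.n_clones,
        n_hecs=len(hecs),
        hec_impact=float(hecs["frequency"].sum() * 100.0),
        depth=r.total_molecules,
    )


def summarize_cohort(
    reps: list[Repertoire], threshold: float = DEFAULT_HEC_THRESHOLD
) -> pd.DataFrame:
    """Summary table over samples, carrying sample metadata columns."""
    rows = []
    for r in reps:
        s = summarize(r, threshold)
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": r.meta.patient_id,
                "joint": r.meta.joint,
                "compartment": r.meta.compartment,
                "depth": s.depth,
                "n_clones": s.n_clones,
                "n_hecs": s.n_hecs,
                "hec_impact": s.hec_impact,
            }
        )
    return pd.DataFrame(rows)
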