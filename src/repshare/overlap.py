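"""Pairwise repertoire similarity: top-N clonal retrieval and the
Chao-modified abundance-based Sørensen index.

Both statistics compare two samples on CDR3-only clone keys at equal
sequencing depth.

Top-N clonal retrieval takes each sample's N most expanded clones
(deterministic tie-break: molecule count descending, then CDR3
lexicographic) and reports the percentage of the N keys present in both
top lists. With equal list sizes the measure is symmetric.

The Chao-modified Sørensen index estimates the similarity of the *full*
repertoires from the relative abundances of shared clones, correcting
for shared clones missed by incomplete sampling. With shared clones
having counts X_i (out of n molecules) in sample A and Y_i (out of m)
in sample B,

    U = sum_i X_i/n + ((m-1)/m) * (f+1 / (2 f+2)) * sum_{i: Y_i=1} X_i/n
    V = sum_i Y_i/m + ((n-1)/n) * (f1+ / (2 f2+)) * sum_{i: X_i=1} Y_i/m

where f+1 / f+2 count shared clones that are singletons / doubletons in
B, and f1+ / f2+ the same in A. U and V estimate the total relative
abundance in each sample of the clones shared with the other, so they
are capped at 1; when a doubleton count is zero it is replaced by 1
(the EstimateS convention). The abundance-based Sørensen index is then

    L = 2UV / (U + V),   L = 0 when no clones are shared.

Values near 0 mean no overlap; values near 1 mean the two repertoires
are effectively identical in composition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .clonotyping import Repertoire, project_to_cdr3
from .io_airr import SampleMeta

__all__ = [
    "ChaoComponents",
    "OverlapResult",
    "shared_clone_table",
    "topn_retrieval",
    "chao_sorensen",
    "classical_sorensen",
    "overlap_plot_data",
    "classify_pair",
    "pairwise_overlaps",
    "overlaps_to_frame",
]

logger = logging.getLogger(__name__)

COMPARISON_CLASSES = (
    "ST_ST_within_joint",
    "ST_ST_between_joints",
    "ST_SF",
    "ST_PB",
    "SF_PB",
    "other",
)


@dataclass(frozen=True)
class ChaoComponents:
    """Intermediate quantities of the Chao-Sørensen estimator, for audit."""

    U: float
    V: float
    f_plus1: int  # shared clones that are singletons in B
    f_plus2: int  # shared clones that are doubletons in B
    f_1plus: int  # shared clones that are singletons in A
    f_2plus: int  # shared clones that are doubletons in A
    n: int
    m: int
    n_shared: int


@dataclass
class OverlapResult:
    """All similarity statistics for one within-patient sample pair."""

    sample_a: str
    sample_b: str
    patient_id: str
    comparison_class: str
    depth: int
    n_top: int
    effective_n_top: int
    topn_retrieval: float
    chao_sorensen: float
    components: ChaoComponents
    shared_clones: pd.DataFrame


def _cdr3_counts(r: Repertoire) -> pd.Series:
    """CDR3 -> molecule count; projects V/J-resolved repertoires first."""
    rep = r if r.is_cdr3_projected else project_to_cdr3(r)
    return rep.clones.set_index("cdr3")["molecule_count"]


def shared_clone_table(a: Repertoire, b: Repertoire) -> pd.DataFrame:
    """Abundance pairs (count_a, count_b) for every CDR3 shared by a and b."""
    ca, cb = _cdr3_counts(a), _cdr3_counts(b)
    shared = ca.index.intersection(cb.index).sort_values()
    t = pd.DataFrame(
        {
            "cdr3": shared,
            "count_a": ca.loc[shared].to_numpy(),
            "count_b": cb.loc[shared].to_numpy(),
        }
    )
    t["freq_a"] = t["count_a"] / a.total_molecules
    t["freq_b"] = t["count_b"] / b.total_molecules
    t["is_singleton_in_a"] = t["count_a"] == 1
    t["is_doubleton_in_a"] = t["count_a"] == 2
    t["is_singleton_in_b"] = t["count_b"] == 1
    t["is_doubleton_in_b"] = t["count_b"] == 2
    return t


def _top_keys(r: Repertoire, n: int) -> set[str]:
    """Top-n CDR3 keys; clone table order is the deterministic rank order."""
    rep = r if r.is_cdr3_projected else project_to_cdr3(r)
    return set(rep.clones["cdr3"].iloc[:n])


def topn_retrieval(a: Repertoire, b: Repertoire, n: int = 25) -> float:
    """Percentage of the top-n clones found in both samples' top-n lists.

    If either sample has fewer than n clones the comparison is made over
    the largest common list size and a warning is logged.
    """
    if a.total_molecules != b.total_molecules:
        raise ValueError(
            f"samples {a.meta.sample_id} and {b.meta.sample_id} are at "
            f"unequal depth ({a.total_molecules} vs {b.total_molecules})"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    n_eff = min(n, a.n_clones, b.n_clones)
    if n_eff < n:
        logger.warning(
            "top-%d retrieval for (%s, %s) computed over n=%d (fewer clones than requested)",
            n, a.meta.sample_id, b.meta.sample_id, n_eff,
        )
    inter = _top_keys(a, n_eff) & _top_keys(b, n_eff)
    return 100.0 * len(inter) / n_eff


def chao_sorensen(
    a: Repertoire,
    b: Repertoire,
    variant: Literal["bias_corrected", "uncorrected"] = "bias_corrected",
) -> tuple[float, ChaoComponents]:
    """Abundance-based Chao-Sørensen similarity of two repertoires.

    Returns the index in [0, 1] together with its audit components (U,
    V, singleton/doubleton counts). ``variant="uncorrected"`` drops the
    unseen-shared-clone correction term, leaving U = sum X_i/n.
    """
    if a.n_clones == 0 or b.n_clones == 0:
        raise ValueError("chao_sorensen: empty repertoire")
    t = shared_clone_table(a, b)
    n, m = a.total_molecules, b.total_molecules
    x = t["count_a"].to_numpy(dtype=float)
    y = t["count_b"].to_numpy(dtype=float)
    f_plus1 = int((y == 1).sum())
    f_plus2 = int((y == 2).sum())
    f_1plus = int((x == 1).sum())
    f_2plus = int((x == 2).sum())

    u = float((x / n).sum())
    v = float((y / m).sum())
    if variant == "bias_corrected":
        u += ((m - 1) / m) * (f_plus1 / (2 * max(f_plus2, 1))) * float((x / n)[y == 1].sum())
        v += ((n - 1) / n) * (f_1plus / (2 * max(f_2plus, 1))) * float((y / m)[x == 1].sum())
    elif variant != "uncorrected":
        raise ValueError(f"unknown variant {variant!r}")
    u = min(u, 1.0)
    v = min(v, 1.0)
    index = 0.0 if (u + v) == 0 else 2 * u * v / (u + v)
    comp = ChaoComponents(
        U=u, V=v,
        f_plus1=f_plus1, f_plus2=f_plus2, f_1plus=f_1plus, f_2plus=f_2plus,
        n=n, m=m, n_shared=len(t),
    )
    return index, comp


def classical_sorensen(a: Repertoire, b: Repertoire) -> float:
    """Incidence-based Sørensen 2|A∩B|/(|A|+|B|) on CDR3 sets (limit check)."""
    sa, sb = set(_cdr3_counts(a).index), set(_cdr3_counts(b).index)
    if not sa and not sb:
        return 0.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def overlap_plot_data(
    a: Repertoire,
    b: Repertoire,
    nd_floor: float | None = None,
    hec_threshold: float = 0.005,
) -> pd.DataFrame:
    """Per-clone frequency pairs for an overlap scatter plot.

    One row per CDR3 in the union of the two samples, with frequencies
    as percentages. A clone absent from one sample is placed at the
    ``nd_floor`` pseudo-frequency (default: half the minimum observable
    frequency, 0.5/depth) and flagged not-detected; the flag keeps the
    floor out of any statistic. Each row carries a quadrant label
    relative to the HEC threshold line (default 0.5%).
    """
    if a.total_molecules != b.total_molecules:
        raise ValueError("overlap_plot_data requires equal depth")
    if nd_floor is None:
        nd_floor = 0.5 / a.total_molecules
    fa = _cdr3_counts(a) / a.total_molecules
    fb = _cdr3_counts(b) / b.total_molecules
    union = fa.index.union(fb.index).sort_values()
    fa = fa.reindex(union)
    fb = fb.reindex(union)
    nd_a = fa.isna()
    nd_b = fb.isna()
    fa = fa.fillna(nd_floor)
    fb = fb.fillna(nd_floor)
    hec_a = (fa >= hec_threshold) & ~nd_a
    hec_b = (fb >= hec_threshold) & ~nd_b
    quadrant = np.select(
        [hec_a & hec_b, hec_a & ~hec_b, ~hec_a & hec_b],
        ["both-HEC", "HEC-a-only", "HEC-b-only"],
        default="neither",
    )
    return pd.DataFrame(
        {
            "cdr3": union,
            "freq_a_pct": fa.to_numpy() * 100.0,
            "freq_b_pct": fb.to_numpy() * 100.0,
            "nd_a": nd_a.to_numpy(),
            "nd_b": nd_b.to_numpy(),
            "quadrant": quadrant,
        }
    )


def classify_pair(a: SampleMeta, b: SampleMeta) -> str:
    """Comparison class of a within-patient sample pair."""
    comps = {a.compartment, b.compartment}
    st = {"ST_SP", "ST_IP"}
    if comps <= st:
        return "ST_ST_within_joint" if a.joint == b.joint else "ST_ST_between_joints"
    if comps & st and "SF" in comps:
        return "ST_SF"
    if comps & st and "PB" in comps:
        return "ST_PB"
    if comps == {"SF", "PB"}:
        return "SF_PB"
    return "other"


def pairwise_overlaps(
    cohort: list[Repertoire],
    n_top: int = 25,
    variant: Literal["bias_corrected", "uncorrected"] = "bias_corrected",
) -> list[OverlapResult]:
    """All within-patient pairwise overlap statistics for a cohort.

    Samples must share one common depth (unequal-depth pairs are an
    error); pairs are never formed across patients. Pair order within a
    patient follows the cohort order.
    """
    results = []
    for a, b in itertools.combinations(cohort, 2):
        if a.meta.patient_id != b.meta.patient_id:
            continue
        if a.total_molecules != b.total_molecules:
            raise ValueError(
                f"pair ({a.meta.sample_id}, {b.meta.sample_id}) at unequal depth"
            )
        pa = a if a.is_cdr3_projected else project_to_cdr3(a)
        pb = b if b.is_cdr3_projected else project_to_cdr3(b)
        n_eff = min(n_top, pa.n_clones, pb.n_clones)
        index, comp = chao_sorensen(pa, pb, variant=variant)
        results.append(
            OverlapResult(
                sample_a=a.meta.sample_id,
                sample_b=b.meta.sample_id,
                patient_id=a.meta.patient_id,
                comparison_class=classify_pair(a.meta, b.meta),
                depth=a.total_molecules,
                n_top=n_top,
                effective_n_top=n_eff,
                topn_retrieval=topn_retrieval(pa, pb, n_top),
                chao_sorensen=index,
                components=comp,
                shared_clones=shared_clone_table(pa, pb),
            )
        )
    return results


def overlaps_to_frame(results: list[OverlapResult]) -> pd.DataFrame:
    """Flat overlap table (one row per pair) for serialization."""
    rows = []
    for r in results:
        c = r.components
        rows.append(
            {
                "sample_a": r.sample_a,
                "sample_b": r.sample_b,
                "patient_id": r.patient_id,
                "comparison_class": r.comparison_class,
                "depth": r.depth,
                "n_top": r.n_top,
                "effective_n_top": r.effective_n_top,
                "topn_retrieval_pct": r.topn_retrieval,
                "chao_sorensen": r.chao_sorensen,
                "n_shared_clones": c.n_shared,
                "U": c.U,
                "V": c.V,
                "f_plus1": c.f_plus1,
                "f_plus2": c.f_plus2,
                "f_1plus": c.f_1plus,
                "f_2plus": c.f_2plus,
            }
        )
    return pd.DataFrame(rows)
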