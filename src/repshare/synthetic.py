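"""Synthetic multi-compartment BCR repertoire cohorts with known truth.

The generator emulates the sampling design of a paired-compartment
arthritis cohort: per patient, synovial-tissue biopsies from two sites
(suprapatellar SP, infrapatellar IP) in each of two knee joints,
synovial fluid from one joint, and peripheral blood. Every generated
molecule traces to exactly one ground-truth clone, so estimator
behaviour (clone richness, HEC detection, top-N retrieval, Chao-
Sørensen) can be tested against known sharing structure.

Model
-----
Each sample owns a clone pool of ``richness`` ranks with a heavy-tailed
abundance profile: rank-quantile lognormal (flatter head) or Zipf
(power-law). The shape parameter is solved numerically so that the
expected number of pool clones at relative abundance >= 0.5% equals the
configured ``hec_target``. Clone *identities* (CDR3 + V/J) are patient
private; sharing between paired samples is modelled at the identity
level: when sample B is paired to sample A with sharing probability
rho, each rank of B carries, with probability rho, the clone identity
of the same rank in A (correlated dominance), otherwise a fresh private
identity. Plasma-cell-like expression amplification is modelled by
multiplying a random small fraction of tissue/fluid clone weights by a
factor drawn from a 5-50x range before normalization.

Sequencing of a sample draws ``molecules`` molecules multinomially from
the abundance profile; each molecule gets a unique 12-nt UMI and a raw-
read multiplicity (1 + Poisson), emitted as one AIRR-style record per
molecule. Everything is reproducible from ``master_seed``; per-sample
streams are derived from (master_seed, sample_id) so adding patients
never perturbs existing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .io_airr import DEFAULT_DIALECT, RECORD_COLUMNS, SampleMeta, write_table
from .repertoire_stats import derive_seed

__all__ = [
    "CompartmentProfile",
    "SharingConfig",
    "SyntheticCohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "abundance_profile",
    "solve_shape",
    "generate_cohort",
    "recover_parameters",
]

_V_GENES = (
    "IGHV1-2", "IGHV1-69", "IGHV2-5", "IGHV3-7", "IGHV3-23",
    "IGHV3-30", "IGHV4-34", "IGHV4-39", "IGHV5-51", "IGHV6-1",
)
_J_GENES = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")
_BASES = np.array(list("ACGT"))
_UMI_LENGTH = 12
_HEC_THRESHOLD = 0.005


@dataclass(frozen=True)
class CompartmentProfile:
    """Abundance/depth profile of one compartment.

    ``richness`` is the clone-pool size; ``hec_target`` the expected
    number of pool clones at frequency >= 0.5% (the shape parameter is
    solved to match it, unless ``shape`` is given explicitly);
    ``hec_mass`` the expected summed frequency of those clones, kept as
    a declared expectation for recovery reports; ``molecules`` the
    sequencing depth before downstream depth standardization.
    """

    richness: int
    hec_target: float
    hec_mass: float
    molecules: int = 20_000
    abundance: Literal["zipf", "lognormal"] = "lognormal"
    shape: float | None = None

    def __post_init__(self) -> None:
        if self.richness < 1 or self.molecules < 1:
            raise ValueError("richness and molecules must be positive")
        if not (0 <= self.hec_mass <= 1):
            raise ValueError("hec_mass must be in [0, 1]")
        if self.abundance not in ("zipf", "lognormal"):
            raise ValueError(f"unknown abundance model {self.abundance!r}")


@dataclass(frozen=True)
class SharingConfig:
    """Probabilities that a clone of one sample recurs in a paired sample."""

    rho_within_joint: float = 0.25
    rho_between_joints: float = 0.15
    rho_st_sf: float = 0.20
    rho_blood: float = 0.03

    def __post_init__(self) -> None:
        for name in ("rho_within_joint", "rho_between_joints", "rho_st_sf", "rho_blood"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _default_profiles() -> dict[str, CompartmentProfile]:
    st = CompartmentProfile(richness=4_000, hec_target=30, hec_mass=0.55)
    return {
        "ST_SP": st,
        "ST_IP": st,
        "SF": CompartmentProfile(richness=8_000, hec_target=23, hec_mass=0.32),
        "PB": CompartmentProfile(
            richness=12_000, hec_target=5, hec_mass=0.16, abundance="zipf"
        ),
    }


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full cohort-generation configuration.

    ``design="full"`` gives each patient 2 joints x (SP + IP) + SF + PB
    (six samples); ``design="pair"`` gives a single joint's SP + IP
    pair, for focused sharing experiments.
    """

    n_patients: int = 2
    master_seed: int = 0
    profiles: dict[str, CompartmentProfile] = field(default_factory=_default_profiles)
    sharing: SharingConfig = field(default_factory=SharingConfig)
    design: Literal["full", "pair"] = "full"
    umi_reads_mean: float = 3.0
    plasma_fraction: float = 0.02
    plasma_amplification_range: tuple[float, float] = (5.0, 50.0)
    cdr3_length_range: tuple[int, int] = (30, 60)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.plasma_amplification_range
        if lo > hi:
            raise ValueError("plasma_amplification_range low must be <= high")
        if not (0 <= self.plasma_fraction <= 1):
            raise ValueError("plasma_fraction must be in [0, 1]")
        missing = {"ST_SP", "ST_IP", "SF", "PB"} - set(self.profiles)
        if self.design == "full" and missing:
            raise ValueError(f"profiles missing compartments: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "profiles" in raw:
            raw["profiles"] = {
                comp: CompartmentProfile(**block) for comp, block in raw["profiles"].items()
            }
        if "sharing" in raw:
            raw["sharing"] = SharingConfig(**raw["sharing"])
        for key in ("plasma_amplification_range", "cdr3_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@lru_cache(maxsize=64)
def solve_shape(kind: str, richness: int, hec_target: float) -> float:
    """Shape parameter whose expected >=0.5% clone count matches the target.

    Grid search (step 0.01) over sigma in [0.3, 4] (lognormal) or the
    exponent s in [0.3, 3] (Zipf), minimizing the absolute deviation of
    the analytic HEC count from ``hec_target``; ties resolve to the
    flattest profile.
    """
    grid = np.arange(0.3, 4.0 if kind == "lognormal" else 3.0, 0.01)
    best_shape, best_err = grid[0], np.inf
    for shape in grid:
        p = abundance_profile(kind, richness, float(shape))
        err = abs(int((p >= _HEC_THRESHOLD).sum()) - hec_target)
        if err < best_err:
            best_shape, best_err = float(shape), err
    return best_shape


def abundance_profile(kind: str, richness: int, shape: float) -> np.ndarray:
    """Deterministic rank-ordered clone abundance vector (sums to 1)."""
    ranks = np.arange(1, richness + 1, dtype=float)
    if kind == "zipf":
        w = ranks ** (-shape)
    elif kind == "lognormal":
        q = (ranks - 0.5) / richness
        w = np.exp(shape * norm.ppf(1.0 - q))
    else:
        raise ValueError(f"unknown abundance model {kind!r}")
    return w / w.sum()


@dataclass
class GroundTruth:
    """True clone identities and abundances behind a synthetic cohort."""

    #: clone_id -> (patient_id, cdr3, v_gene, j_gene)
    registry: pd.DataFrame
    #: sample_id -> DataFrame(rank, clone_id, probability), rank-ordered
    samples: dict[str, pd.DataFrame]

    def top_ids(self, sample_id: str, n: int) -> set[int]:
        return set(self.samples[sample_id]["clone_id"].iloc[:n])

    def true_top_sharing(self, sample_a: str, sample_b: str, n: int = 25) -> float:
        """True top-n retrieval (%) from the underlying abundance ranks."""
        inter = self.top_ids(sample_a, n) & self.top_ids(sample_b, n)
        return 100.0 * len(inter) / n

    def true_shared_mass(self, sample_a: str, sample_b: str) -> tuple[float, float]:
        """True total abundance in each sample of clones shared with the other."""
        ta, tb = self.samples[sample_a], self.samples[sample_b]
        shared = set(ta["clone_id"]) & set(tb["clone_id"])
        ua = float(ta.loc[ta["clone_id"].isin(shared), "probability"].sum())
        ub = float(tb.loc[tb["clone_id"].isin(shared), "probability"].sum())
        return ua, ub

    def dominant_ids(self, sample_id: str, threshold: float = _HEC_THRESHOLD) -> set[int]:
        t = self.samples[sample_id]
        return set(t.loc[t["probability"] >= threshold, "clone_id"])


@dataclass
class SyntheticCohort:
    """In-memory generated cohort: records per sample, manifest, truth."""

    config: SyntheticCohortConfig
    manifest: list[SampleMeta]
    records: dict[str, pd.DataFrame]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        """Emit AIRR TSVs (one per sample), manifest CSV and truth TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        inv = {k: v for k, v in DEFAULT_DIALECT.items()}
        for sid, df in self.records.items():
            airr = df.rename(columns={k: inv[k] for k in df.columns if k in inv})
            airr = airr.drop(columns=["cdr3_aa"], errors="ignore")
            write_table(airr, out / f"{sid}.tsv")
        manifest = pd.DataFrame(
            [
                {
                    "sample_id": m.sample_id,
                    "patient_id": m.patient_id,
                    "joint": m.joint,
                    "compartment": m.compartment,
                    "collection_day": m.collection_day,
                }
                for m in self.manifest
            ]
        )
        write_table(manifest, out / "manifest.csv", sep=",")
        truth_rows = []
        reg = self.truth.registry.set_index("clone_id")
        for sid, t in self.truth.samples.items():
            tt = t.copy()
            tt.insert(0, "sample_id", sid)
            tt["cdr3"] = reg.loc[tt["clone_id"], "cdr3"].to_numpy()
            truth_rows.append(tt)
        write_table(pd.concat(truth_rows, ignore_index=True), out / "ground_truth.tsv")


class _CloneRegistry:
    """Per-patient factory of globally unique clone identities."""

    def __init__(self, cfg: SyntheticCohortConfig, patient_idx: int, patient_id: str):
        self.cfg = cfg
        self.patient_id = patient_id
        # 8-nt patient barcode prefix precludes cross-patient CDR3 collisions
        digits = np.base_repr(patient_idx, base=4).zfill(8)[-8:]
        self.barcode = "".join(_BASES[int(d)] for d in digits)
        self.rng = np.random.default_rng(
            derive_seed(cfg.master_seed, f"pool/{patient_id}")
        )
        self.cdr3s: list[str] = []
        self.v: list[str] = []
        self.j: list[str] = []
        self._seen: set[str] = set()

    def fresh(self, k: int) -> np.ndarray:
        """Mint k new clone ids with unique CDR3s and random V/J calls."""
        lo, hi = self.cfg.cdr3_length_range
        start = len(self.cdr3s)
        made = 0
        attempts = 0
        while made < k:
            attempts += 1
            if attempts > 50 * k + 100:
                raise RuntimeError("exhausted retries generating unique CDR3s")
            length = int(self.rng.integers(lo, hi + 1))
            body = "".join(_BASES[self.rng.integers(0, 4, length - 8)])
            cdr3 = self.barcode + body
            if cdr3 in self._seen:
                continue
            self._seen.add(cdr3)
            self.cdr3s.append(cdr3)
            self.v.append(_V_GENES[int(self.rng.integers(0, len(_V_GENES)))])
            self.j.append(_J_GENES[int(self.rng.integers(0, len(_J_GENES)))])
            made += 1
        return np.arange(start, start + k)


def _sample_identities(
    rng: np.random.Generator,
    registry: _CloneRegistry,
    richness: int,
    parent_ids: np.ndarray | None,
    rho: float,
) -> np.ndarray:
    """Rank -> clone-id assignment, copying parent ranks with prob rho."""
    ids = np.empty(richness, dtype=int)
    if parent_ids is None or rho == 0.0:
        return registry.fresh(richness)
    n_copy = min(richness, len(parent_ids))
    copy_mask = np.zeros(richness, dtype=bool)
    copy_mask[:n_copy] = rng.random(n_copy) < rho
    ids[copy_mask] = parent_ids[: richness][copy_mask[:n_copy]]
    n_fresh = int((~copy_mask).sum())
    ids[~copy_mask] = registry.fresh(n_fresh)
    return ids


def _int_to_umi(values: np.ndarray) -> list[str]:
    out = []
    for v in values:
        chars = []
        for _ in range(_UMI_LENGTH):
            chars.append("ACGT"[v & 3])
            v >>= 2
        out.append("".join(chars))
    return out


def _draw_sample(
    cfg: SyntheticCohortConfig,
    registry: _CloneRegistry,
    meta: SampleMeta,
    profile: CompartmentProfile,
    parent_ids: np.ndarray | None,
    rho: float,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Generate one sample: records frame, identity array, true probabilities."""
    rng = np.random.default_rng(derive_seed(cfg.master_seed, f"synth/{meta.sample_id}"))
    shape = profile.shape
    if shape is None:
        shape = solve_shape(profile.abundance, profile.richness, profile.hec_target)
    probs = abundance_profile(profile.abundance, profile.richness, shape)
    if meta.compartment in ("ST_SP", "ST_IP", "SF") and cfg.plasma_fraction > 0:
        lo, hi = cfg.plasma_amplification_range
        mask = rng.random(profile.richness) < cfg.plasma_fraction
        w = probs.copy()
        w[mask] *= rng.uniform(lo, hi, int(mask.sum()))
        probs = w / w.sum()
    ids = _sample_identities(rng, registry, profile.richness, parent_ids, rho)

    counts = rng.multinomial(profile.molecules, probs)
    clone_idx = np.repeat(np.arange(profile.richness), counts)

    n_mol = profile.molecules
    umi_ints = np.array([], dtype=np.int64)
    while len(umi_ints) < n_mol:
        extra = rng.integers(0, 4**_UMI_LENGTH, size=int(n_mol * 1.1) + 64)
        umi_ints = np.unique(np.concatenate([umi_ints, extra]))
    umi_ints = rng.permutation(umi_ints)[:n_mol]

    reads = 1 + rng.poisson(max(cfg.umi_reads_mean - 1.0, 0.0), n_mol)
    cdr3_arr = np.array(registry.cdr3s, dtype=object)
    v_arr = np.array(registry.v, dtype=object)
    j_arr = np.array(registry.j, dtype=object)
    mol_ids = ids[clone_idx]
    frame = pd.DataFrame(
        {
            "sample_id": meta.sample_id,
            "umi": _int_to_umi(umi_ints),
            "cdr3_nt": cdr3_arr[mol_ids],
            "v_gene": v_arr[mol_ids],
            "j_gene": j_arr[mol_ids],
            "cdr3_aa": None,
            "duplicate_count": reads,
        }
    )[list(RECORD_COLUMNS)]
    return frame, ids, probs


def generate_cohort(cfg: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a reproducible multi-patient, multi-compartment cohort."""
    manifest: list[SampleMeta] = []
    records: dict[str, pd.DataFrame] = {}
    truth_samples: dict[str, pd.DataFrame] = {}
    registries: list[_CloneRegistry] = []

    rho = cfg.sharing
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:02d}"
        registry = _CloneRegistry(cfg, p, pid)
        registries.append(registry)
        if cfg.design == "full":
            plan = [
                # (suffix, joint, compartment, parent suffix, rho)
                ("J1_SP", "left_knee", "ST_SP", None, 0.0),
                ("J1_IP", "left_knee", "ST_IP", "J1_SP", rho.rho_within_joint),
                ("J2_SP", "right_knee", "ST_SP", "J1_SP", rho.rho_between_joints),
                ("J2_IP", "right_knee", "ST_IP", "J2_SP", rho.rho_within_joint),
                ("SF", "left_knee", "SF", "J1_SP", rho.rho_st_sf),
                ("PB", "other", "PB", "J1_SP", rho.rho_blood),
            ]
        else:
            plan = [
                ("J1_SP", "left_knee", "ST_SP", None, 0.0),
                ("J1_IP", "left_knee", "ST_IP", "J1_SP", rho.rho_within_joint),
            ]
        id_by_suffix: dict[str, np.ndarray] = {}
        for suffix, joint, compartment, parent, pair_rho in plan:
            sid = f"{pid}_{suffix}"
            meta = SampleMeta(
                sample_id=sid, patient_id=pid, joint=joint, compartment=compartment
            )
            parent_ids = id_by_suffix[parent] if parent else None
            frame, ids, probs = _draw_sample(
                cfg, registry, meta, cfg.profiles[compartment], parent_ids, pair_rho
            )
            id_by_suffix[suffix] = ids
            manifest.append(meta)
            records[sid] = frame
            truth_samples[sid] = pd.DataFrame(
                {
                    "rank": np.arange(1, len(ids) + 1),
                    "clone_id": ids,
                    "probability": probs,
                }
            )

    reg_frames = []
    offset = 0
    for p, registry in enumerate(registries):
        n = len(registry.cdr3s)
        reg_frames.append(
            pd.DataFrame(
                {
                    "clone_id": np.arange(n) + offset,
                    "patient_id": registry.patient_id,
                    "cdr3": registry.cdr3s,
                    "v_gene": registry.v,
                    "j_gene": registry.j,
                }
            )
        )
        # shift this patient's sample clone_ids into the global id space
        pid = registry.patient_id
        for sid in list(truth_samples):
            if sid.startswith(pid + "_"):
                truth_samples[sid] = truth_samples[sid].assign(
                    clone_id=truth_samples[sid]["clone_id"] + offset
                )
        offset += n
    registry_frame = pd.concat(reg_frames, ignore_index=True)
    truth = GroundTruth(registry=registry_frame, samples=truth_samples)
    return SyntheticCohort(config=cfg, manifest=manifest, records=records, truth=truth)


def recover_parameters(
    cohort: SyntheticCohort,
    overlap_results,
    n_top: int = 25,
) -> pd.DataFrame:
    """Estimated vs true sharing per analysed sample pair.

    For each overlap result, reports the pipeline's top-N retrieval and
    Chao-Sørensen estimate next to the ground-truth top-N sharing and
    the true Sørensen-type similarity 2*U*V/(U+V) computed from the
    generator's abundance vectors (U, V = true shared mass per sample).
    """
    truth = cohort.truth
    rows = []
    for r in overlap_results:
        true_top = truth.true_top_sharing(r.sample_a, r.sample_b, n_top)
        ua, ub = truth.true_shared_mass(r.sample_a, r.sample_b)
        true_sor = 0.0 if (ua + ub) == 0 else 2 * ua * ub / (ua + ub)
        rows.append(
            {
                "sample_a": r.sample_a,
                "sample_b": r.sample_b,
                "comparison_class": r.comparison_class,
                "est_topn_retrieval_pct": r.topn_retrieval,
                "true_topn_sharing_pct": true_top,
                "est_chao_sorensen": r.chao_sorensen,
                "true_sorensen": true_sor,
                "topn_error": r.topn_retrieval - true_top,
                "chao_error": r.chao_sorensen - true_sor,
            }
        )
    return pd.DataFrame(rows)
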