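"""Top-N retrieval and Chao-Sørensen estimator vs independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repshare.clonotyping import project_to_cdr3
from repshare.io_airr import SampleMeta
from repshare.overlap import (
    chao_sorensen,
    classical_sorensen,
    classify_pair,
    overlap_plot_data,
    pairwise_overlaps,
    shared_clone_table,
    topn_retrieval,
)

from conftest import make_repertoire


def oracle_chao_sorensen(counts_a: dict, counts_b: dict) -> float:
    """Brute-force, from-the-formula evaluation of the bias-corrected
    abundance-based Sørensen estimator (independent of the implementation).
    """
    n = sum(counts_a.values())
    m = sum(counts_b.values())
    shared = sorted(set(counts_a) & set(counts_b))
    if not shared:
        return 0.0
    X = {k: counts_a[k] for k in shared}
    Y = {k: counts_b[k] for k in shared}
    f_p1 = sum(1 for k in shared if Y[k] == 1)
    f_p2 = sum(1 for k in shared if Y[k] == 2)
    f_1p = sum(1 for k in shared if X[k] == 1)
    f_2p = sum(1 for k in shared if X[k] == 2)
    U = sum(X[k] / n for k in shared) + ((m - 1) / m) * (
        f_p1 / (2 * (f_p2 if f_p2 > 0 else 1))
    ) * sum(X[k] / n for k in shared if Y[k] == 1)
    V = sum(Y[k] / m for k in shared) + ((n - 1) / n) * (
        f_1p / (2 * (f_2p if f_2p > 0 else 1))
    ) * sum(Y[k] / m for k in shared if X[k] == 1)
    U = min(U, 1.0)
    V = min(V, 1.0)
    return 0.0 if U + V == 0 else 2 * U * V / (U + V)


def cdr3_name(i: int) -> str:
    return "TGT" + "".join("ACGT"[int(d)] for d in np.base_repr(i, base=4).zfill(5))


def pair_of_reps(counts_a, counts_b):
    a = make_repertoire(counts_a, SampleMeta("A", "P01", "left_knee", "ST_SP"))
    b = make_repertoire(counts_b, SampleMeta("B", "P01", "left_knee", "ST_IP"))
    return project_to_cdr3(a), project_to_cdr3(b)


class TestChaoSorensen:
    def test_hand_example(self):
        """A={a:4,b:1,c:5}, B={a:3,b:6,d:1}: U=0.5, V capped at 1, index 2/3."""
        a, b = pair_of_reps({"TGTA": 4, "TGTC": 1, "TGTG": 5},
                            {"TGTA": 3, "TGTC": 6, "TGTT": 1})
        val, comp = chao_sorensen(a, b)
        assert comp.U == pytest.approx(0.5, abs=1e-12)
        assert comp.V == pytest.approx(1.0, abs=1e-12)
        assert val == pytest.approx(2 / 3, abs=1e-12)

    def test_disjoint_is_zero(self):
        a, b = pair_of_reps({"TGTA": 5, "TGTC": 5}, {"TGTG": 5, "TGTT": 5})
        val, comp = chao_sorensen(a, b)
        assert val == 0.0 and comp.n_shared == 0

    def test_identical_counts_ge3_is_one(self):
        counts = {cdr3_name(i): 3 + i for i in range(10)}
        a, b = pair_of_reps(counts, counts)
        val, comp = chao_sorensen(a, b)
        assert comp.U == 1.0 and comp.V == 1.0
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_tables(self):
        """100 random paired count tables agree with the formula to 1e-12."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            na, nb = rng.integers(2, 31, size=2)
            universe = [cdr3_name(i) for i in range(40)]
            keys_a = rng.choice(40, size=na, replace=False)
            keys_b = rng.choice(40, size=nb, replace=False)
            counts_a = {universe[k]: int(rng.integers(1, 51)) for k in keys_a}
            counts_b = {universe[k]: int(rng.integers(1, 51)) for k in keys_b}
            a, b = pair_of_reps(counts_a, counts_b)
            val, _ = chao_sorensen(a, b)
            assert val == pytest.approx(oracle_chao_sorensen(counts_a, counts_b), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        counts_a = {cdr3_name(i): int(rng.integers(1, 20)) for i in range(15)}
        counts_b = {cdr3_name(i): int(rng.integers(1, 20)) for i in range(5, 25)}
        a, b = pair_of_reps(counts_a, counts_b)
        assert chao_sorensen(a, b)[0] == pytest.approx(chao_sorensen(b, a)[0], abs=1e-15)

    def test_uncorrected_variant_drops_correction(self):
        a, b = pair_of_reps({"TGTA": 4, "TGTC": 1, "TGTG": 5},
                            {"TGTA": 3, "TGTC": 6, "TGTT": 1})
        val, comp = chao_sorensen(a, b, variant="uncorrected")
        assert comp.U == pytest.approx(0.5) and comp.V == pytest.approx(0.9)
        assert val == pytest.approx(2 * 0.5 * 0.9 / 1.4, abs=1e-12)

    def test_empty_errors(self):
        a, _ = pair_of_reps({"TGTA": 1}, {"TGTA": 1})
        import pandas as pd
        from repshare.clonotyping import Repertoire
        empty = Repertoire(
            meta=SampleMeta("E", "P01", "left_knee", "ST_SP"),
            clones=a.clones.iloc[0:0],
            total_molecules=0,
        )
        with pytest.raises(ValueError):
            chao_sorensen(a, empty)

    def test_converges_to_one_with_depth_on_shared_distribution(self):
        """Two samples from one clone distribution: index rises toward 1 with depth."""
        rng = np.random.default_rng(11)
        p = np.arange(1, 301, dtype=float) ** -1.1
        p /= p.sum()
        medians = []
        for depth in (500, 5_000):
            vals = []
            for seed in range(50):
                r = np.random.default_rng(seed)
                ca = r.multinomial(depth, p)
                cb = r.multinomial(depth, p)
                counts_a = {cdr3_name(i): int(c) for i, c in enumerate(ca) if c > 0}
                counts_b = {cdr3_name(i): int(c) for i, c in enumerate(cb) if c > 0}
                a, b = pair_of_reps(counts_a, counts_b)
                vals.append(chao_sorensen(a, b)[0])
            medians.append(np.median(vals))
        assert medians[1] > medians[0]
        assert medians[1] > 0.9

    @settings(max_examples=50, deadline=None)
    @given(
        counts_a=st.dictionaries(st.integers(0, 15), st.integers(1, 30), min_size=1, max_size=12),
        counts_b=st.dictionaries(st.integers(0, 15), st.integers(1, 30), min_size=1, max_size=12),
    )
    def test_range_property(self, counts_a, counts_b):
        a, b = pair_of_reps(
            {cdr3_name(k): v for k, v in counts_a.items()},
            {cdr3_name(k): v for k, v in counts_b.items()},
        )
        val, comp = chao_sorensen(a, b)
        assert 0.0 <= val <= 1.0
        assert 0.0 <= comp.U <= 1.0 and 0.0 <= comp.V <= 1.0


def test_uv_terms_match_vegan_reference(tmp_path):
    """U and V agree with R/vegan's abundance-based Chao estimator.

    vegan::vegdist(method="chao") implements the Jaccard-type form
    1 - UV/(U+V-UV) with the same bias-corrected U and V terms, so it
    independently validates the components behind the Sørensen form.
    """
    import json
    import shutil
    import subprocess

    assert shutil.which("Rscript"), "Rscript expected on PATH"
    rng = np.random.default_rng(17)
    tables = []
    for _ in range(5):
        a = np.zeros(30, int)
        b = np.zeros(30, int)
        ka = rng.choice(30, int(rng.integers(5, 15)), replace=False)
        kb = rng.choice(30, int(rng.integers(5, 15)), replace=False)
        a[ka] = rng.integers(1, 40, ka.size)
        b[kb] = rng.integers(1, 40, kb.size)
        tables.append((a.tolist(), b.tolist()))
    payload = tmp_path / "tables.json"
    payload.write_text(json.dumps(tables))
    script = f"""
    suppressMessages(library(vegan)); suppressMessages(library(jsonlite))
    tabs <- fromJSON("{payload.as_posix()}", simplifyVector=TRUE)
    for (i in seq_len(dim(tabs)[1])) {{
      m <- rbind(tabs[i,1,], tabs[i,2,])
      cat(sprintf("%.15f\\n", as.numeric(vegdist(m, method="chao"))))
    }}
    """
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    vegan_sims = [1.0 - float(x) for x in out.stdout.split()]
    for (ca, cb), ref in zip(tables, vegan_sims):
        counts_a = {cdr3_name(i): c for i, c in enumerate(ca) if c > 0}
        counts_b = {cdr3_name(i): c for i, c in enumerate(cb) if c > 0}
        a, b = pair_of_reps(counts_a, counts_b)
        _, comp = chao_sorensen(a, b)
        u, v = comp.U, comp.V
        jaccard = 0.0 if (u + v - u * v) == 0 else u * v / (u + v - u * v)
        assert jaccard == pytest.approx(ref, abs=1e-10)


class TestTopNRetrieval:
    def test_identical(self):
        counts = {cdr3_name(i): 30 - i for i in range(30)}
        a, b = pair_of_reps(counts, counts)
        assert topn_retrieval(a, b, 25) == 100.0

    def test_disjoint(self):
        a, b = pair_of_reps({cdr3_name(i): 30 - i for i in range(30)},
                            {cdr3_name(100 + i): 30 - i for i in range(30)})
        assert topn_retrieval(a, b, 25) == 0.0

    def test_five_of_twentyfive_shared(self):
        """b's top-25 = {c1..c5} + 20 private: retrieval 5/25 = 20%."""
        shared = {cdr3_name(i): 100 - i for i in range(5)}
        a_counts = {**shared, **{cdr3_name(10 + i): 50 - i for i in range(20)}}
        b_counts = {**shared, **{cdr3_name(200 + i): 50 - i for i in range(20)}}
        # equalize depth
        assert sum(a_counts.values()) == sum(b_counts.values())
        a, b = pair_of_reps(a_counts, b_counts)
        assert topn_retrieval(a, b, 25) == pytest.approx(20.0)

    def test_symmetric_and_range(self):
        rng = np.random.default_rng(8)
        ca = {cdr3_name(i): int(c) for i, c in enumerate(rng.integers(1, 40, 40))}
        cb = {cdr3_name(i + 20): int(c) for i, c in enumerate(rng.integers(1, 40, 40))}
        da, db = sum(ca.values()), sum(cb.values())
        ca[cdr3_name(999)] = ca.get(cdr3_name(999), 0) + max(db - da, 0) + 1
        cb[cdr3_name(998)] = cb.get(cdr3_name(998), 0) + max(da - db, 0) + 1
        a, b = pair_of_reps(ca, cb)
        r1, r2 = topn_retrieval(a, b, 25), topn_retrieval(b, a, 25)
        assert r1 == r2
        assert 0.0 <= r1 <= 100.0

    def test_fewer_clones_than_n_uses_effective_n(self, caplog):
        a, b = pair_of_reps({"TGTA": 5, "TGTC": 5}, {"TGTA": 6, "TGTG": 4})
        import logging
        with caplog.at_level(logging.WARNING):
            val = topn_retrieval(a, b, 25)
        assert val == pytest.approx(100.0 * 1 / 2)
        assert any("n=2" in r.getMessage() for r in caplog.records)

    def test_unequal_depth_errors(self):
        a, b = pair_of_reps({"TGTA": 5}, {"TGTA": 6})
        with pytest.raises(ValueError, match="depth"):
            topn_retrieval(a, b, 25)

    def test_adding_shared_top_clone_never_decreases(self):
        """Replacing a private top clone by a shared one is monotone."""
        base_a = {cdr3_name(i): 100 - i for i in range(25)}
        depth_pad = {cdr3_name(500): 1}
        for k in range(0, 26, 5):
            shared_keys = [cdr3_name(i) for i in range(k)]
            b_counts = {key: 100 - i for i, key in enumerate(shared_keys)}
            b_counts.update({cdr3_name(300 + i): 70 - i for i in range(25 - k)})
            pad = sum(base_a.values()) + 1 - sum(b_counts.values())
            b_counts[cdr3_name(600)] = pad
            a, b = pair_of_reps({**base_a, **depth_pad}, b_counts)
            # cdr3_name(600) pad clone may enter b's top-25; retrieval >= k-1 of 25
            assert topn_retrieval(a, b, 25) >= 100.0 * max(k - 1, 0) / 25


class TestClassicalSorensenLimit:
    def test_identical_sets(self):
        counts = {cdr3_name(i): 2 for i in range(10)}
        a, b = pair_of_reps(counts, counts)
        assert classical_sorensen(a, b) == 1.0

    def test_half_shared(self):
        a, b = pair_of_reps({cdr3_name(i): 2 for i in range(10)},
                            {cdr3_name(i + 5): 2 for i in range(10)})
        assert classical_sorensen(a, b) == pytest.approx(0.5)


class TestOverlapPlotData:
    def test_union_rows_nd_floor_and_quadrants(self):
        a, b = pair_of_reps(
            {"TGTA": 500, "TGTC": 400, "TGTG": 100},   # depth 1000
            {"TGTA": 555, "TGTT": 444, "TGTG": 1},     # TGTG at 0.1% in b
        )
        t = overlap_plot_data(a, b)
        assert len(t) == 4  # union of CDR3s
        row_c = t[t["cdr3"] == "TGTC"].iloc[0]
        assert row_c["nd_b"] and row_c["freq_b_pct"] == pytest.approx(100 * 0.5 / 1000)
        row_a = t[t["cdr3"] == "TGTA"].iloc[0]
        assert row_a["quadrant"] == "both-HEC"
        row_g = t[t["cdr3"] == "TGTG"].iloc[0]
        assert row_g["quadrant"] == "HEC-a-only"
        assert not row_g["nd_a"] and not row_g["nd_b"]

    def test_nd_never_counts_as_hec(self):
        a, b = pair_of_reps({"TGTA": 99, "TGTC": 1}, {"TGTA": 99, "TGTG": 1})
        t = overlap_plot_data(a, b, nd_floor=0.02)  # floor above threshold on purpose
        row = t[t["cdr3"] == "TGTC"].iloc[0]
        assert row["nd_b"] and row["quadrant"] == "HEC-a-only"


class TestPairwiseOverlaps:
    def _meta(self, sid, pid, joint, comp):
        return SampleMeta(sid, pid, joint, comp)

    def test_classification(self):
        cases = [
            (("ST_SP", "left_knee"), ("ST_IP", "left_knee"), "ST_ST_within_joint"),
            (("ST_SP", "left_knee"), ("ST_SP", "right_knee"), "ST_ST_between_joints"),
            (("ST_IP", "left_knee"), ("SF", "left_knee"), "ST_SF"),
            (("ST_SP", "left_knee"), ("PB", "other"), "ST_PB"),
            (("SF", "left_knee"), ("PB", "other"), "SF_PB"),
        ]
        for (ca, ja), (cb, jb), expected in cases:
            a = self._meta("A", "P01", ja, ca)
            b = self._meta("B", "P01", jb, cb)
            assert classify_pair(a, b) == expected
            assert classify_pair(b, a) == expected

    def test_patient_scoping_and_classes(self):
        counts = {cdr3_name(i): 10 for i in range(10)}
        reps = [
            make_repertoire(counts, self._meta("A", "P01", "left_knee", "ST_SP")),
            make_repertoire(counts, self._meta("B", "P01", "left_knee", "ST_IP")),
            make_repertoire(counts, self._meta("C", "P01", "other", "PB")),
            make_repertoire(counts, self._meta("D", "P02", "left_knee", "ST_SP")),
        ]
        reps = [project_to_cdr3(r) for r in reps]
        results = pairwise_overlaps(reps)
        pairs = {(r.sample_a, r.sample_b) for r in results}
        assert pairs == {("A", "B"), ("A", "C"), ("B", "C")}
        classes = sorted(r.comparison_class for r in results)
        assert classes == ["ST_PB", "ST_PB", "ST_ST_within_joint"]

    def test_unequal_depth_pair_errors(self):
        a = make_repertoire({"TGTA": 10}, self._meta("A", "P01", "left_knee", "ST_SP"))
        b = make_repertoire({"TGTA": 11}, self._meta("B", "P01", "left_knee", "ST_IP"))
        with pytest.raises(ValueError, match="unequal depth"):
            pairwise_overlaps([project_to_cdr3(a), project_to_cdr3(b)])


def test_shared_clone_table_flags():
    a, b = pair_of_reps({"TGTA": 1, "TGTC": 2, "TGTG": 7},
                        {"TGTA": 2, "TGTC": 1, "TGTT": 7})
    t = shared_clone_table(a, b).set_index("cdr3")
    assert set(t.index) == {"TGTA", "TGTC"}
    assert bool(t.loc["TGTA", "is_singleton_in_a"]) and bool(t.loc["TGTA", "is_doubleton_in_b"])
    assert bool(t.loc["TGTC", "is_doubleton_in_a"]) and bool(t.loc["TGTC", "is_singleton_in_b"])
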