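import pandas as pd
import pytest

from repshare.clonotyping import build_repertoire
from repshare.io_airr import RECORD_COLUMNS, SampleMeta


@pytest.fixture
def meta_st_sp():
    return SampleMeta("S1", "P01", "left_knee", "ST_SP")


@pytest.fixture
def meta_st_ip():
    return SampleMeta("S2", "P01", "left_knee", "ST_IP")


def make_records(counts, sample_id="S1", v_gene="IGHV3-23", j_gene="IGHJ4"):
    """One molecule row per unit of count, each with its own UMI.

    ``counts`` maps cdr3 (or (cdr3, v, j) tuples) to molecule counts.
    """
    rows = []
    i = 0
    for key, c in counts.items():
        if isinstance(key, tuple):
            cdr3, v, j = key
        else:
            cdr3, v, j = key, v_gene, j_gene
        for _ in range(c):
            rows.append((sample_id, f"UMI{i:06d}", cdr3, v, j, None, 1))
            i += 1
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def make_repertoire(counts, meta=None, **kwargs):
    meta = meta or SampleMeta("S1", "P01", "left_knee", "ST_SP")
    return build_repertoire(make_records(counts, sample_id=meta.sample_id, **kwargs), meta)


@pytest.fixture
def make_records_fixture():
    return make_records


@pytest.fixture
def make_repertoire_fixture():
    return make_repertoire
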