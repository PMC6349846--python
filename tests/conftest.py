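import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from grousescan.popdata import SampleTable, SiteMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def build_site_matrix(
    dosage,
    samples=None,
    chrom="chr1",
    positions=None,
    depth=None,
    chrom_length=None,
    aa=None,
):
    """Hand-build a SiteMatrix from a dosage array (sites x samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, k = dosage.shape
    if samples is None:
        samples = [f"s{i}" for i in range(k)]
    if positions is None:
        positions = np.arange(1, n + 1, dtype=np.int64) * 100
    return SiteMatrix(
        chrom=np.full(n, chrom, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ancestral=np.full(n, "A", dtype=object),
        derived=np.full(n, "G", dtype=object),
        dosage=dosage,
        samples=list(samples),
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        chrom_lengths=None if chrom_length is None else {chrom: chrom_length},
        aa=np.asarray(aa, dtype=object) if aa is not None else None,
    )


def sample_table(pops: dict[str, int], coverage: float | None = None) -> SampleTable:
    rows = []
    for pop, k in pops.items():
        for i in range(k):
            rows.append({"sample_id": f"{pop}_{i}", "population": pop})
    frame = pd.DataFrame(rows)
    if coverage is not None:
        frame["mean_coverage"] = coverage
    return SampleTable(frame)


@pytest.fixture
def tiny_neutral():
    from grousescan.simulate import make_fixture

    return make_fixture("tiny-neutral")


@pytest.fixture
def tiny_sweeps():
    from grousescan.simulate import make_fixture

    return make_fixture("tiny-sweeps")
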