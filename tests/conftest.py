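import numpy as np
import pytest

from spongescope.interactome import FilterThresholds, GeneRecord
from spongescope.mre import MIR16

TIMEPOINTS = (0.0, 6.0, 12.0, 24.0, 48.0)


@pytest.fixture
def mirna():
    return MIR16


@pytest.fixture
def thresholds():
    return FilterThresholds()


def make_record(
    gene_id="G1",
    reads_mir16=150,
    reads_mirctr=50,
    basal_expr=20.0,
    late_logfc=0.0,
    timepoints=TIMEPOINTS,
):
    """GeneRecord whose late-window (24/48 h) mean logFC equals ``late_logfc``."""
    logfc = {t: 0.0 for t in timepoints}
    logfc[timepoints[-1]] = late_logfc
    logfc[timepoints[-2]] = late_logfc
    return GeneRecord(gene_id, reads_mir16, reads_mirctr, basal_expr, logfc)


def random_records(rng: np.random.Generator, n: int) -> list[GeneRecord]:
    """Random gene records deliberately concentrated around every threshold."""
    records = []
    ip = rng.choice([0, 50, 99, 100, 101, 150, 500, 5000], size=n)
    ctr = rng.choice([0, 100, 499, 500, 501, 600, 5000], size=n)
    basal = rng.choice([0.0, 5.0, 9.99, 10.0, 10.01, 20.0, 500.0], size=n)
    late = rng.choice([-2.0, -0.8, -0.51, -0.5, -0.49, 0.0, 0.49, 0.5, 0.51, 0.8, 2.0], size=n)
    early = rng.normal(0, 0.3, size=(n, 3))
    for i in range(n):
        logfc = {
            0.0: early[i, 0],
            6.0: early[i, 1],
            12.0: early[i, 2],
            24.0: late[i] + rng.choice([-0.1, 0.0, 0.1]),
            48.0: 0.0,
        }
        logfc[48.0] = 2 * late[i] - logfc[24.0]  # force exact late mean
        records.append(
            GeneRecord(f"G{i}", int(ip[i]), int(ctr[i]), float(basal[i]), logfc)
        )
    return records


def brute_force_label(rec: GeneRecord, thr: FilterThresholds) -> str:
    """Independent single-pass evaluation of the four printed predicates."""
    tps = sorted(rec.logfc)
    late = (rec.logfc[tps[-1]] + rec.logfc[tps[-2]]) / 2.0
    bound = rec.reads_mir16 > thr.min_ip_reads
    down = late < -thr.abs_logfc
    up = late > thr.abs_logfc
    clean = rec.reads_mirctr <= thr.max_ctr_reads
    expressed = rec.basal_expr > thr.min_basal
    if bound and down:
        return "target" if clean else "excluded_false_positive"
    if bound and up:
        if not clean:
            return "excluded_false_positive"
        return "sponge_candidate" if expressed else "interactant_up"
    return "none"
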