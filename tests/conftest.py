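import io

import numpy as np
import pytest

from sorcna.cna_io import CaseSet, ClinicalRecord, CnaCall
from sorcna.genome import GenomeBuild, Cytoband, load_hg18


@pytest.fixture(scope="session")
def hg18():
    return load_hg18()


@pytest.fixture()
def toy_build():
    """Two chromosomes (chr1:100, chr2:50) with p/q split at 60 and 30."""
    return GenomeBuild(
        build_name="toy",
        chromosomes=[("chr1", 100), ("chr2", 50)],
        cytobands=[
            Cytoband("chr1", 1, 60, "p1", "p"),
            Cytoband("chr1", 61, 100, "q1", "q"),
            Cytoband("chr2", 1, 30, "p1", "p"),
            Cytoband("chr2", 31, 50, "q1", "q"),
        ],
    )


def make_clinical(case_ids, **overrides):
    records = []
    for i, cid in enumerate(case_ids):
        records.append(
            ClinicalRecord(
                case_id=cid,
                grade=overrides.get("grade", ["II", "III"][i % 2]),
                stage=overrides.get("stage", ["A", "B", "C"][i % 3]),
                recurrence=overrides.get("recurrence", ["yes", "no"][i % 2]),
                time=float(overrides.get("time", 12 + i)),
                event=overrides.get("event", ["dead", "censored"][i % 2]),
            )
        )
    return records


@pytest.fixture()
def two_call_case_set():
    """Case A gain [10,50], case B gain [30,80] on chr1, n_cases = 2."""
    calls = [
        CnaCall("A", "chr1", 10, 50, "gain"),
        CnaCall("B", "chr1", 30, 80, "gain"),
    ]
    return CaseSet(calls=calls, clinical=make_clinical(["A", "B"]))


def random_case_set(rng, n_cases=6, chrom_len=1000, max_calls_per_case=4,
                    chromosomes=("chr1", "chr2")):
    """Small random cohort for oracle comparisons; same-direction overlaps
    are merged by CaseSet, opposite-direction overlaps are avoided by
    assigning one direction per (case, chromosome)."""
    case_ids = [f"C{i}" for i in range(n_cases)]
    calls = []
    for cid in case_ids:
        for chrom in chromosomes:
            direction = "gain" if rng.random() < 0.5 else "loss"
            for _ in range(rng.integers(0, max_calls_per_case + 1)):
                start = int(rng.integers(1, chrom_len))
                end = int(rng.integers(start, min(start + 300, chrom_len) + 1))
                calls.append(CnaCall(cid, chrom, start, end, direction))
    return CaseSet(calls=calls, clinical=make_clinical(case_ids))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
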