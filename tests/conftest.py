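import numpy as np
import pytest

from mirclass.seqio import BINARY, NUMERIC, FeatureTable, MiRNARecord, TargetGeneMap


@pytest.fixture
def toy_records():
    return [
        MiRNARecord(id="hsa-miR-21-3p", sequence="CAACACCAGUCGAUGGGCUGU"),
        MiRNARecord(id="hsa-miR-32-3p", sequence="CAAUUUAGUGUGUGUGAUAUU"),
        MiRNARecord(id="hsa-let-7a-3p", sequence="CUAUACAAUCUACUGUCUUUC"),
    ]


@pytest.fixture
def class_copy_table():
    """One binary attribute identical to the class, balanced 10+10."""
    n = 20
    values = np.array([[1.0]] * 10 + [[0.0]] * 10)
    labels = np.array(["positive"] * 10 + ["negative"] * 10, dtype=object)
    return FeatureTable(
        ids=[f"m{i}" for i in range(n)],
        attributes=[("copy", BINARY)],
        values=values,
        labels=labels,
    )


@pytest.fixture
def toy_targets():
    targets = TargetGeneMap()
    targets.add("hsa-miR-21-3p", "MAPK1", 92.0)
    targets.add("hsa-miR-21-3p", "TP53INP1", 85.0)
    targets.add("hsa-miR-32-3p", "PTEN", 90.0)
    targets.add("hsa-miR-32-3p", "GSK3B", 70.0)
    targets.add("hsa-let-7a-3p", "PIM1", 81.0)
    return targets


def random_feature_table(rng, n=12, p=4, binary=False, labeled=True):
    if binary:
        values = rng.integers(0, 2, size=(n, p)).astype(float)
        kinds = [BINARY] * p
    else:
        values = rng.normal(size=(n, p))
        kinds = [NUMERIC] * p
    labels = None
    if labeled:
        labels = np.asarray(
            ["positive" if v else "negative" for v in rng.integers(0, 2, size=n)],
            dtype=object,
        )
    return FeatureTable(
        ids=[f"m{i}" for i in range(n)],
        attributes=[(f"a{j}", kinds[j]) for j in range(p)],
        values=values,
        labels=labels,
    )
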