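import numpy as np
import pandas as pd
import pytest

import paradiv as pv


@pytest.fixture(scope="session")
def vent_fixture() -> pv.DissectionDataset:
    return pv.vent_composition()


@pytest.fixture(scope="session")
def scores() -> pv.OrderedScores:
    """Ordered alternative: kelp > atoll > vent (scores low to high)."""
    return pv.OrderedScores.from_ordering(["vent", "atoll", "kelp"])


@pytest.fixture(scope="session")
def study_dataset() -> pv.DissectionDataset:
    """One harmonized study-scale simulated dataset, shared across tests."""
    ds = pv.simulate_dataset(pv.study_scale_config(seed=7))
    return pv.apply_inclusion_filters(ds, pv.FilterSpec())


def _annotations(rows):
    df = pd.DataFrame(
        rows, columns=["morphogroup_id", "parasite_taxon", "life_cycle", "life_stage"]
    )
    df["redundancy_group"] = None
    return df


@pytest.fixture
def toy_dataset() -> pv.DissectionDataset:
    """Two host species (one fish, one mollusk), three hosts, two morphogroups."""
    records = pd.DataFrame(
        {
            "host_individual_id": ["f1", "f2", "m1"],
            "host_species": ["sculpin", "sculpin", "snail"],
            "host_group": ["fish", "fish", "mollusk"],
            "ecosystem": ["kelp", "kelp", "kelp"],
            "site": ["s1", "s1", "s1"],
            "collection_date": [None, None, None],
            "host_length_mm": [120.0, 90.0, 15.0],
        }
    )
    observations = pd.DataFrame(
        {
            "host_individual_id": ["f1", "m1"],
            "morphogroup_id": ["trem_a", "trem_b"],
            "count": [3, 1],
        }
    )
    annotations = _annotations(
        [
            ("trem_a", "Trematoda", "ILC", "adult"),
            ("trem_b", "Trematoda", "ILC", "sporocyst"),
        ]
    )
    return pv.make_dataset(records, observations, annotations)


def make_records(spec, ecosystem="kelp", length=50.0):
    """spec: list of (species, group, n_individuals). Deterministic records."""
    rows = []
    for sp, group, n in spec:
        for j in range(n):
            rows.append(
                {
                    "host_individual_id": f"{sp}_h{j:03d}",
                    "host_species": sp,
                    "host_group": group,
                    "ecosystem": ecosystem,
                    "site": "s1",
                    "collection_date": None,
                    "host_length_mm": length + j,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def make_records_factory():
    return make_records


@pytest.fixture
def annotations_factory():
    return _annotations


def random_incidence(rng, m, s, p=0.4):
    """Random binary incidence matrix with no empty morphogroup columns."""
    mat = (rng.random((m, s)) < p).astype(np.int8)
    empty = np.flatnonzero(mat.sum(axis=0) == 0)
    for j in empty:
        mat[rng.integers(m), j] = 1
    return pv.IncidenceMatrix(
        [f"u{i}" for i in range(m)], [f"p{j}" for j in range(s)], mat
    )


@pytest.fixture
def random_incidence_factory():
    return random_incidence
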