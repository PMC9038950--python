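"""Shared fixtures: a small synthetic cohort with planted events, generated
once per session, plus its parsed form."""

from __future__ import annotations

import pytest

from plastomics import read_cohort
from plastomics.synth import (CohortConfig, GCShift, Inversion, IRExpand,
                              Loss, generate_cohort)

NDH_GENES = ("ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhG", "ndhH",
             "ndhI", "ndhJ", "ndhK")

# LSC indices 5..8 are atpA, atpF, atpH, atpI in the default reference order
DEMO_EVENTS = (
    ((0, 1, 2), Loss("infA")),
    *tuple(((3,), Loss(g)) for g in NDH_GENES),
    ((4, 5), Inversion(6, 8)),          # breaks the atpA-atpF-atpH-atpI block
    ((6,), IRExpand(("rps19",))),       # rps19 becomes IR-duplicated
    ((7,), GCShift(3, 0.10)),
)


@pytest.fixture(scope="session")
def demo_cohort_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("demo_cohort")
    cfg = CohortConfig(n_genomes=12, seed=11, events=DEMO_EVENTS)
    truth = generate_cohort(cfg, d)
    return d, truth


@pytest.fixture(scope="session")
def demo_truth(demo_cohort_dir):
    return demo_cohort_dir[1]


@pytest.fixture(scope="session")
def demo_parsed(demo_cohort_dir):
    d, _ = demo_cohort_dir
    return read_cohort(d, d / "taxonomy.tsv")
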