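"""Shared fixtures: small hand-built cohorts and graphs."""

import numpy as np
import pytest

from smile.pedigree import Cohort, Family, Individual
from smile.spatial import build_location_graph


def make_individual(iid, fid, role, loc="A", sex=None, birth_year=None, months=84):
    if sex is None:
        sex = {"father": "M", "mother": "F"}.get(role, "M")
    if birth_year is None:
        birth_year = {"father": 1965, "mother": 1967}.get(role, 1995)
    return Individual(iid, fid, role, sex, birth_year, months, loc)


def make_family(fid, n_parents=2, n_children=2, loc="A", child_years=None):
    members = []
    if n_parents >= 1:
        members.append(make_individual(f"{fid}_f", fid, "father", loc))
    if n_parents >= 2:
        members.append(make_individual(f"{fid}_m", fid, "mother", loc))
    years = child_years or [1994 + i for i in range(n_children)]
    for i in range(n_children):
        members.append(
            make_individual(f"{fid}_c{i}", fid, "child", loc, birth_year=years[i]))
    return Family(fid, members)


@pytest.fixture
def quad_family():
    return make_family("q1", 2, 2)


@pytest.fixture
def trio_family():
    return make_family("t1", 2, 1)


@pytest.fixture
def toy_cohort():
    """Three families (quad, trio, singleton father) over two locations."""
    return Cohort([
        make_family("f1", 2, 2, loc="A"),
        make_family("f2", 2, 1, loc="B"),
        make_family("f3", 1, 0, loc="B"),
    ])


@pytest.fixture
def two_location_graph():
    return build_location_graph([("A", "B")], ["A", "B"])


@pytest.fixture
def mixed_cohort():
    """Varied family signatures over a 4-location path graph."""
    fams = []
    specs = [(2, 2, "A"), (2, 1, "B"), (1, 2, "C"), (2, 3, "D"),
             (1, 0, "A"), (0, 1, "B"), (2, 2, "C"), (2, 0, "D")]
    for i, (np_, nc, loc) in enumerate(specs):
        fams.append(make_family(f"m{i}", np_, nc, loc=loc))
    return Cohort(fams)


@pytest.fixture
def path_graph():
    return build_location_graph(
        [("A", "B"), ("B", "C"), ("C", "D")], ["A", "B", "C", "D"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240625)
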