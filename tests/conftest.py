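import numpy as np
import pytest

from traitspace.io import (
    GrowthForm,
    SpeciesRecord,
    Status,
    phylogeny_from_newick,
)


def make_record(species_id, genus="G1", family="F1", growth_form="non_tree",
                status="native", sla=10.0, height_max=0.5, seed_weight=1.0):
    return SpeciesRecord(
        species_id=species_id,
        genus=genus,
        family=family,
        growth_form=GrowthForm(growth_form),
        status=Status(status),
        sla=sla,
        height_max=height_max,
        seed_weight=seed_weight,
    )


@pytest.fixture
def star_tree():
    return phylogeny_from_newick("(A,B,C,D,E);")


@pytest.fixture
def balanced_tree():
    return phylogeny_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
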