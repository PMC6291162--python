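import pathlib

import pytest

from ralascope import packaged_data
from ralascope.cohort_io import read_cohort
from ralascope.structure_contacts import read_region_list

#: screened-trio sites in the packaged site table (SiteC is excluded)
SCREENED_SITES = {"SiteA", "SiteB", "SiteD", "SiteE", "SiteF"}


@pytest.fixture(scope="session")
def table1_cohort():
    """The packaged 11-proband cohort transcription with phenotype flags."""
    return read_cohort(
        packaged_data("table1_variants.tsv"),
        packaged_data("table1_phenotypes.tsv"),
    )


@pytest.fixture(scope="session")
def synthetic_region():
    """Packaged 24-residue stand-in binding region on a 206-aa protein."""
    return read_region_list(packaged_data("region_rala_synthetic.txt"), 206)


@pytest.fixture()
def population_variants_file(tmp_path, synthetic_region):
    """34 variant residues, all outside the synthetic region."""
    outside = sorted(set(range(1, 207)) - set(synthetic_region.residues))[:34]
    path = tmp_path / "population_variants.txt"
    path.write_text("".join(f"{r}\n" for r in outside), encoding="utf-8")
    return path
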