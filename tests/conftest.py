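import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from clocknet import generate_cohort, study_like_config, synthetic


ALIASES_TEXT = """\
MIMAT0000250\thsa-miR-139;hsa-miR-139-5p
MIMAT0004552\thsa-miR-139*;hsa-miR-139-3p
MIMAT0000730\thsa-miR-378;hsa-miR-378a-5p
MIMAT0000731\thsa-miR-378;hsa-miR-378a-3p
MIMAT0000066\thsa-let-7e;hsa-let-7e-5p
MIMAT0000762\thsa-miR-325;hsa-miR-325-5p
"""


@pytest.fixture
def alias_file(tmp_path):
    path = tmp_path / "aliases.txt"
    path.write_text(ALIASES_TEXT)
    return path


@pytest.fixture(scope="session")
def study_cohort():
    """One seeded study-like cohort (14 pairs) plus its planted truth."""
    return generate_cohort(study_like_config(seed=11, n_mirnas=80))


@pytest.fixture(scope="session")
def study_fixture_dir(tmp_path_factory, study_cohort):
    """The same cohort written out as the on-disk TSV/JSON fixture."""
    out = tmp_path_factory.mktemp("fixture")
    pset, truth = study_cohort
    synthetic.write_fixture(pset, truth, out)
    return out
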