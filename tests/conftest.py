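import pytest

from parayield.design import StudyDesign, reference_params
from parayield.simulate import (
    generate_clutch_outcomes,
    generate_fecundity,
    generate_survival,
)


@pytest.fixture(scope="session")
def september_design():
    return StudyDesign(collections=("september",))


@pytest.fixture(scope="session")
def september_params():
    return reference_params("september")


@pytest.fixture(scope="session")
def september_tables(september_design, september_params):
    subj = generate_survival(september_design, september_params, 101)
    cont = generate_fecundity(september_design, september_params, 102, subjects=subj)
    clutch = generate_clutch_outcomes(september_design, september_params, 103)
    return {"subjects": subj, "containers": cont, "clutches": clutch}
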