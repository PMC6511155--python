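import pytest

from glycoplan.core import Coding, PatientProfile
from glycoplan.knowledge import load_knowledge_base


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture
def adult_profile():
    return PatientProfile(
        id="adult-1", age=30, sex="male", weight=70.0, height=175.0,
        lifestyle="moderately_active", education_level="high",
        regimen_preference="IIT",
    )


@pytest.fixture
def pregnant_profile():
    return PatientProfile(
        id="preg-1", age=28, sex="female", pregnant=True,
        weight=62.0, height=165.0, regimen_preference="fixed_twice",
    )


@pytest.fixture
def child_profile():
    return PatientProfile(
        id="child-1", age=8, sex="female", weight=30.0, height=130.0,
        education_level="low",
    )


@pytest.fixture
def fixed_twice_profile():
    return PatientProfile(
        id="df-1", age=40, sex="male", weight=30.0, height=160.0,
        regimen_preference="fixed_twice",
    )


def coded(code: str, system: str = "SNOMEDCT", display: str = "") -> Coding:
    return Coding(system=system, code=code, display=display)
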