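import pathlib

import pytest

from ontorel.ontology import load_obo

FIXTURE_OBO = """format-version: 1.2
ontology: test

[Term]
id: T:0
name: alpha

[Term]
id: T:1
name: beta
is_a: T:0 ! alpha

[Term]
id: T:2
name: gamma
is_a: T:0

[Term]
id: T:3
name: delta
is_a: T:1

[Term]
id: T:4
name: epsilon
is_a: T:1
is_a: T:2

[Term]
id: T:5
name: zeta
is_a: T:3
"""

FIXTURE_XML = """<?xml version="1.0" encoding="UTF-8"?>
<corpus>
  <document id="DrugBank.d0">
    <sentence id="DrugBank.d0.s0"
              text="Aspirin increases the effect of warfarin but not of heparin">
      <entity id="d0.s0.e0" charOffset="0-6" type="drug" text="Aspirin"/>
      <entity id="d0.s0.e1" charOffset="32-39" type="drug" text="warfarin"/>
      <entity id="d0.s0.e2" charOffset="52-58" type="drug" text="heparin"/>
      <pair id="d0.s0.p0" e1="d0.s0.e0" e2="d0.s0.e1" ddi="true" type="effect"/>
      <pair id="d0.s0.p1" e1="d0.s0.e0" e2="d0.s0.e2" ddi="false"/>
      <pair id="d0.s0.p2" e1="d0.s0.e1" e2="d0.s0.e2" ddi="false"/>
    </sentence>
  </document>
</corpus>
"""


@pytest.fixture(scope="session")
def fixture_obo_path(tmp_path_factory) -> pathlib.Path:
    p = tmp_path_factory.mktemp("onto") / "fixture.obo"
    p.write_text(FIXTURE_OBO)
    return p


@pytest.fixture(scope="session")
def fixture_graph(fixture_obo_path):
    return load_obo(fixture_obo_path)


@pytest.fixture()
def fixture_xml_path(tmp_path) -> pathlib.Path:
    p = tmp_path / "fixture.xml"
    p.write_text(FIXTURE_XML)
    return p
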