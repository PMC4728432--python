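"""Shared fixtures: tiny hand-built networks and paired SBML/tabular files."""

import textwrap

import pytest

from fluxscape import parse_gpr
from fluxscape.model import MetabolicModel, Metabolite, Reaction

# Chain A -> B with uptake and secretion: EX1 -> R2 -> EX3, all [0, 10].
CHAIN_TABULAR = textwrap.dedent("""\
    reaction_id\tequation\tlower_bound\tupper_bound\tgpr_string
    EX1\t -> 1 A_c\t0\t10\t
    R2\t1 A_c -> 1 B_c\t0\t10\tg2
    EX3\t1 B_c -> \t0\t10\t
    """)

# Same chain as SBML Level 3 + fbc (gene product association on R2).
CHAIN_SBML_FBC = textwrap.dedent("""\
    <?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
          xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
          level="3" version="1" fbc:required="false">
      <model id="chain" fbc:strict="true">
        <listOfCompartments>
          <compartment id="c" constant="true"/>
        </listOfCompartments>
        <listOfSpecies>
          <species id="A_c" compartment="c" hasOnlySubstanceUnits="false"
                   boundaryCondition="false" constant="false"/>
          <species id="B_c" compartment="c" hasOnlySubstanceUnits="false"
                   boundaryCondition="false" constant="false"/>
        </listOfSpecies>
        <listOfParameters>
          <parameter id="lb_zero" value="0" constant="true"/>
          <parameter id="ub_ten" value="10" constant="true"/>
        </listOfParameters>
        <fbc:listOfGeneProducts>
          <fbc:geneProduct fbc:id="g2" fbc:label="g2"/>
        </fbc:listOfGeneProducts>
        <listOfReactions>
          <reaction id="EX1" reversible="false" fast="false"
                    fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_ten">
            <listOfProducts>
              <speciesReference species="A_c" stoichiometry="1" constant="true"/>
            </listOfProducts>
          </reaction>
          <reaction id="R2" reversible="false" fast="false"
                    fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_ten">
            <listOfReactants>
              <speciesReference species="A_c" stoichiometry="1" constant="true"/>
            </listOfReactants>
            <listOfProducts>
              <speciesReference species="B_c" stoichiometry="1" constant="true"/>
            </listOfProducts>
            <fbc:geneProductAssociation>
              <fbc:geneProductRef fbc:geneProduct="g2"/>
            </fbc:geneProductAssociation>
          </reaction>
          <reaction id="EX3" reversible="false" fast="false"
                    fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_ten">
            <listOfReactants>
              <speciesReference species="B_c" stoichiometry="1" constant="true"/>
            </listOfReactants>
          </reaction>
        </listOfReactions>
      </model>
    </sbml>
    """)

# Same chain as legacy SBML Level 2: notes GENE_ASSOCIATION + kinetic-law bounds.
CHAIN_SBML_LEGACY = textwrap.dedent("""\
    <?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
      <model id="chain_legacy">
        <listOfCompartments>
          <compartment id="c"/>
        </listOfCompartments>
        <listOfSpecies>
          <species id="A_c" compartment="c"/>
          <species id="B_c" compartment="c"/>
        </listOfSpecies>
        <listOfReactions>
          <reaction id="EX1" reversible="false">
            <listOfProducts>
              <speciesReference species="A_c" stoichiometry="1"/>
            </listOfProducts>
            <kineticLaw>
              <math xmlns="http://www.w3.org/1998/Math/MathML">
                <ci> FLUX_VALUE </ci>
              </math>
              <listOfParameters>
                <parameter id="LOWER_BOUND" value="0"/>
                <parameter id="UPPER_BOUND" value="10"/>
                <parameter id="FLUX_VALUE" value="0"/>
              </listOfParameters>
            </kineticLaw>
          </reaction>
          <reaction id="R2" reversible="false">
            <notes>
              <body xmlns="http://www.w3.org/1999/xhtml">
                <p>GENE_ASSOCIATION: g2</p>
              </body>
            </notes>
            <listOfReactants>
              <speciesReference species="A_c" stoichiometry="1"/>
            </listOfReactants>
            <listOfProducts>
              <speciesReference species="B_c" stoichiometry="1"/>
            </listOfProducts>
            <kineticLaw>
              <math xmlns="http://www.w3.org/1998/Math/MathML">
                <ci> FLUX_VALUE </ci>
              </math>
              <listOfParameters>
                <parameter id="LOWER_BOUND" value="0"/>
                <parameter id="UPPER_BOUND" value="10"/>
                <parameter id="FLUX_VALUE" value="0"/>
              </listOfParameters>
            </kineticLaw>
          </reaction>
          <reaction id="EX3" reversible="false">
            <listOfReactants>
              <speciesReference species="B_c" stoichiometry="1"/>
            </listOfReactants>
            <kineticLaw>
              <math xmlns="http://www.w3.org/1998/Math/MathML">
                <ci> FLUX_VALUE </ci>
              </math>
              <listOfParameters>
                <parameter id="LOWER_BOUND" value="0"/>
                <parameter id="UPPER_BOUND" value="10"/>
                <parameter id="FLUX_VALUE" value="0"/>
              </listOfParameters>
            </kineticLaw>
          </reaction>
        </listOfReactions>
      </model>
    </sbml>
    """)


@pytest.fixture
def chain_model() -> MetabolicModel:
    """EX1 -> R2 (gene g2) -> EX3, all bounds [0, 10]."""
    return MetabolicModel(
        [Metabolite("A_c", "c"), Metabolite("B_c", "c")],
        [
            Reaction("EX1", {"A_c": 1.0}, 0, 10),
            Reaction("R2", {"A_c": -1.0, "B_c": 1.0}, 0, 10, gpr=parse_gpr("g2")),
            Reaction("EX3", {"B_c": -1.0}, 0, 10),
        ],
    )


@pytest.fixture
def t1_model() -> MetabolicModel:
    """Maintenance-forced parallel feeders: EX_A/EX_B [0,10] into M1, DM [1,10]."""
    return MetabolicModel(
        [Metabolite("M1")],
        [
            Reaction("EX_A", {"M1": 1.0}, 0, 10, gpr=parse_gpr("gA")),
            Reaction("EX_B", {"M1": 1.0}, 0, 10, gpr=parse_gpr("gB")),
            Reaction("DM", {"M1": -1.0}, 1, 10),
        ],
    )


@pytest.fixture
def chain_tabular_path(tmp_path):
    path = tmp_path / "chain.tsv"
    path.write_text(CHAIN_TABULAR)
    return path


@pytest.fixture
def chain_sbml_fbc_path(tmp_path):
    path = tmp_path / "chain_fbc.xml"
    path.write_text(CHAIN_SBML_FBC)
    return path


@pytest.fixture
def chain_sbml_legacy_path(tmp_path):
    path = tmp_path / "chain_legacy.xml"
    path.write_text(CHAIN_SBML_LEGACY)
    return path
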