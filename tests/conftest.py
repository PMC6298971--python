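from __future__ import annotations

import pytest

from pulkit.feature_annotation import AnnotationConfig
from pulkit.substrate_rules import default_rule_table
from pulkit.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def config() -> AnnotationConfig:
    return AnnotationConfig()


@pytest.fixture(scope="session")
def rules():
    return default_rule_table()


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study, shared read-only across tests."""
    return generate_dataset(GeneratorConfig(seed=11))


TOY_GFF = """##gff-version 3
##sequence-region c1 1 2000000
c1\tsrc\tCDS\t1\t300\t.\t+\t0\tID=g1
c1\tsrc\tCDS\t400\t900\t.\t-\t0\tID=g2
c1\tsrc\tCDS\t1000\t1600\t.\t+\t0\tID=g3
"""

TOY_SEQS = {"g1": "MKLVINT" * 10, "g2": "ACDEFGHIKL" * 12, "g3": "MSTNPKPQRK" * 15}


@pytest.fixture()
def toy_genome_files(tmp_path):
    gff = tmp_path / "toy.gff3"
    gff.write_text(TOY_GFF)
    faa = tmp_path / "toy.faa"
    faa.write_text("".join(f">{k}\n{v}\n" for k, v in TOY_SEQS.items()))
    return gff, faa
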