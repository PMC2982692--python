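import numpy as np
import pytest

from snpshrink.io import CODE, GenotypeMatrix, SNPMeta

TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: mf root
namespace: molecular_function

[Term]
id: GO:0000002
name: binding
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: catalysis
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000004
name: ion binding
namespace: molecular_function
is_a: GO:0000002

[Term]
id: GO:0000005
name: metal ion binding
namespace: molecular_function
is_a: GO:0000004
relationship: part_of GO:0000003

[Term]
id: GO:0000006
name: kinase activity
namespace: molecular_function
is_a: GO:0000003

[Term]
id: GO:0000007
name: atp binding
namespace: molecular_function
is_a: GO:0000004

[Term]
id: GO:0000010
name: bp root
namespace: biological_process

[Term]
id: GO:0000011
name: signaling
namespace: biological_process
is_a: GO:0000010
"""

#: direct annotations for the 7-term MF DAG plus one BP term
TOY_ANNOTATIONS = {
    "geneA": {"GO:0000005", "GO:0000007"},
    "geneB": {"GO:0000007", "GO:0000006"},
    "geneC": {"GO:0000006"},
    "geneD": {"GO:0000002", "GO:0000011"},
    "geneE": {"GO:0000011"},
}

#: parent relations of the toy MF DAG, for independent oracles
TOY_PARENTS = {
    "GO:0000001": set(),
    "GO:0000002": {"GO:0000001"},
    "GO:0000003": {"GO:0000001"},
    "GO:0000004": {"GO:0000002"},
    "GO:0000005": {"GO:0000004", "GO:0000003"},
    "GO:0000006": {"GO:0000003"},
    "GO:0000007": {"GO:0000004"},
    "GO:0000010": set(),
    "GO:0000011": {"GO:0000010"},
}


def make_matrix(rows, labels=None, snp_ids=None, samples=None):
    """Build a GenotypeMatrix from genotype-string rows like ["AA","Aa",...]."""
    calls = np.array([[CODE[c] for c in row] for row in rows], dtype=np.int8)
    n, p = calls.shape
    return GenotypeMatrix(
        samples=samples or [f"S{i}" for i in range(n)],
        labels=None if labels is None else np.array(labels, dtype=object),
        snps=[SNPMeta(snp_id=(snp_ids[j] if snp_ids else f"snp{j}"),
                      chromosome="1", position=j + 1, alleles=("A", "G"))
              for j in range(p)],
        calls=calls,
    )


@pytest.fixture
def toy_obo_path(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture
def toy_index(toy_obo_path):
    from snpshrink.gosim import build_index

    return build_index(toy_obo_path, TOY_ANNOTATIONS)


@pytest.fixture
def six_sample_matrix():
    """2 classes x 3 samples, 2 SNPs, hand-countable frequencies."""
    return make_matrix(
        rows=[["AA", "Aa"], ["AA", "aa"], ["Aa", "aa"],
              ["aa", "AA"], ["aa", "AA"], ["Aa", "Aa"]],
        labels=["u", "u", "u", "v", "v", "v"],
    )
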