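"""Shared fixtures: small synthetic genomes, annotations and libraries.

Everything is generated programmatically at fixed seeds; the GenBank toy
fixture is written out verbatim so the parser is exercised on text the
package's own writer did not produce.
"""

import textwrap

import pytest

import tnsi


@pytest.fixture(scope="session")
def genome5k():
    """Circular 5-kb random genome used for round-trip tests (circularity
    avoids end-truncation of fragments; seed chosen once)."""
    return tnsi.make_genome(5000, gc=0.5, seed=42, circular=True)


@pytest.fixture(scope="session")
def annotation5k(genome5k):
    return tnsi.make_annotation(genome5k, n_genes=6, mean_gene_len=500, seed=7)


@pytest.fixture(scope="session")
def library5k(annotation5k):
    return tnsi.make_library(annotation5k, seed=11)


def _toy_genbank_sequence():
    import numpy as np

    rng = np.random.default_rng(99)
    return "".join(rng.choice(list("acgt"), size=500))


@pytest.fixture()
def toy_genbank(tmp_path):
    """Hand-written 3-gene GenBank file on a 500-bp linear genome.

    g1: 101..200 forward; g2: complement(221..280); g3 has both a gene and a
    CDS record (the gene record must win); g4 exists only as a CDS.
    """
    seq = _toy_genbank_sequence()
    origin_lines = []
    for i in range(0, 500, 60):
        chunk = seq[i : i + 60]
        blocks = " ".join(textwrap.wrap(chunk, 10))
        origin_lines.append(f"{i + 1:>9} {blocks}")
    text = (
        "LOCUS       toygenome                500 bp    DNA     linear   BCT 01-JAN-1980\n"
        "DEFINITION  hand-written toy genome for parser tests.\n"
        "ACCESSION   toygenome\n"
        "VERSION     toygenome.1\n"
        "KEYWORDS    .\n"
        "SOURCE      synthetic\n"
        "  ORGANISM  synthetic\n"
        "            .\n"
        "FEATURES             Location/Qualifiers\n"
        "     source          1..500\n"
        "     gene            101..200\n"
        '                     /locus_tag="g1"\n'
        "     gene            complement(221..280)\n"
        '                     /locus_tag="g2"\n'
        "     gene            301..360\n"
        '                     /locus_tag="g3"\n'
        "     CDS             301..360\n"
        '                     /locus_tag="g3"\n'
        "     CDS             401..460\n"
        '                     /locus_tag="g4"\n'
        "ORIGIN\n" + "\n".join(origin_lines) + "\n//\n"
    )
    path = tmp_path / "toy.gbk"
    path.write_text(text)
    return path
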