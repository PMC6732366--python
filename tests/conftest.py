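import textwrap

import pytest

# The 13 disease->phenotype annotation rows of the epilepsy example family:
# three OMIM-style diseases sharing two terms (HP:0000006, HP:0002069), so
# the distinct union has 11 terms.
TABLE1_ROWS = [
    ("608217", "EPILEPSY, BENIGN NEONATAL, 3", "HP:0000006"),
    ("608217", "EPILEPSY, BENIGN NEONATAL, 3", "HP:0002069"),
    ("608217", "EPILEPSY, BENIGN NEONATAL, 3", "HP:0003593"),
    ("611277", "GENERALIZED EPILEPSY WITH FEBRILE SEIZURES PLUS, TYPE 3", "HP:0003828"),
    ("611277", "GENERALIZED EPILEPSY WITH FEBRILE SEIZURES PLUS, TYPE 3", "HP:0007359"),
    ("611277", "GENERALIZED EPILEPSY WITH FEBRILE SEIZURES PLUS, TYPE 3", "HP:0000006"),
    ("611277", "GENERALIZED EPILEPSY WITH FEBRILE SEIZURES PLUS, TYPE 3", "HP:0002069"),
    ("611277", "GENERALIZED EPILEPSY WITH FEBRILE SEIZURES PLUS, TYPE 3", "HP:0002121"),
    ("611277", "GENERALIZED EPILEPSY WITH FEBRILE SEIZURES PLUS, TYPE 3", "HP:0010819"),
    ("611277", "GENERALIZED EPILEPSY WITH FEBRILE SEIZURES PLUS, TYPE 3", "HP:0002373"),
    ("267740", "RETINAL DEGENERATION AND EPILEPSY", "HP:0000007"),
    ("267740", "RETINAL DEGENERATION AND EPILEPSY", "HP:0000546"),
    ("267740", "RETINAL DEGENERATION AND EPILEPSY", "HP:0001250"),
]


def make_obo(terms):
    """Render [(term_id, name, parents, obsolete), ...] as OBO text."""
    chunks = ["format-version: 1.2\n"]
    for term_id, name, parents, obsolete in terms:
        stanza = f"[Term]\nid: {term_id}\nname: {name}\n"
        for p in parents:
            stanza += f"is_a: {p}\n"
        if obsolete:
            stanza += "is_obsolete: true\n"
        chunks.append(stanza)
    return "\n".join(chunks)


@pytest.fixture
def toy_obo(tmp_path):
    """Three-term chain: root A <- B <- C."""
    path = tmp_path / "toy.obo"
    path.write_text(
        make_obo(
            [
                ("A", "root", [], False),
                ("B", "middle", ["A"], False),
                ("C", "leaf", ["B"], False),
            ]
        )
    )
    return path


@pytest.fixture
def disease_tsv(tmp_path):
    path = tmp_path / "diseases.tsv"
    lines = ["database_id\tdisease_name\thpo_id"]
    lines += ["\t".join(row) for row in TABLE1_ROWS]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def annotation_writer(tmp_path):
    def _write(rows, name="genes.tsv"):
        path = tmp_path / name
        lines = ["gene_symbol\thpo_id"] + [f"{g}\t{t}" for g, t in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
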