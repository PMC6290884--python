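from pathlib import Path

import pytest

from pdskit.db import MetaboliteRecord, PathwayRecord, build_metabolite_db, build_pathway_db
from pdskit.simulate import generate_toy_db

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def mini_records() -> list[MetaboliteRecord]:
    """Three hand-written metabolite records with known names and synonyms."""
    return [
        MetaboliteRecord(
            hmdb_id="HMDB0000122",
            canonical_name="D-Glucose",
            kegg_id="C00031",
            pubchem_cid="5793",
            synonyms=["blood sugar", "dextrose"],
        ),
        MetaboliteRecord(
            hmdb_id="HMDB0000161",
            canonical_name="L-Alanine",
            kegg_id="C00041",
            synonyms=["alanine", "2-aminopropanoic acid"],
        ),
        MetaboliteRecord(
            hmdb_id="HMDB0000056",
            canonical_name="beta-Alanine",
            synonyms=["3-aminopropanoic acid", "β-alanine"],
        ),
    ]


@pytest.fixture(scope="session")
def mini_db(mini_records):
    return build_metabolite_db(mini_records, version="mini-fixture")


@pytest.fixture(scope="session")
def mini_pathway_db():
    return build_pathway_db(
        [
            PathwayRecord("PW0001", "glycolysis-like", {"HMDB0000122", "HMDB0000161", "HMDB0000056"}),
            PathwayRecord("PW0002", "alanine-like", {"HMDB0000161", "HMDB0000056"}),
            PathwayRecord("PW0003", "sugar-only", {"HMDB0000122"}),
            PathwayRecord("PW0004", "everything", {"HMDB0000122", "HMDB0000161", "HMDB0000056"}),
        ],
        version="mini-pathways",
    )


@pytest.fixture(scope="session")
def toy_dbs():
    """Generated 20-metabolite / 5-pathway databases, deterministic."""
    return generate_toy_db(20, 5, 4, 2, seed=11)
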