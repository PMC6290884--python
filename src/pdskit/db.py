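"""Metabolite-identifier and pathway-membership reference databases.

The pipeline resolves user-supplied metabolite names against a packaged
reference snapshot: a table of metabolites (HMDB accession, canonical name,
cross-references to KEGG / PubChem / METLIN, and synonyms) and a table of
pathways (pathway id, name, member HMDB accessions). Snapshots are plain TSV
so they can be versioned and diffed; remote updating is deliberately out of
scope — provenance comes from the snapshot ``version`` tag carried into every
output.

Name lookup happens on *normalized* strings (see :func:`normalize_name`) so
that case, stray whitespace, typographic dashes and Greek letters do not
defeat exact matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import DatabaseFormatError, NameNormalizationError

logger = logging.getLogger(__name__)

HMDB_ACCESSION_RE = re.compile(r"^HMDB\d{4,}$")

METABOLITE_COLUMNS = [
    "hmdb_id",
    "canonical_name",
    "kegg_id",
    "pubchem_cid",
    "metlin_id",
    "synonyms",
]
PATHWAY_COLUMNS = ["pathway_id", "pathway_name", "members"]

# Greek letters commonly embedded in compound names, spelled out the way
# chemical databases list them.
_GREEK = {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "Α": "alpha",
    "Β": "beta",
    "Γ": "gamma",
}
# Unicode dash family -> ASCII hyphen.
_DASHES = dict.fromkeys("‐‑‒–—―−", "-")
_TRANSLATION = str.maketrans({**_GREEK, **_DASHES})
_WS_RUN = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Canonicalize a metabolite name for index lookup.

    Lower-cases, strips and collapses whitespace, maps Unicode dashes to
    ASCII hyphens and spells out Greek letters (α→alpha, β→beta, γ→gamma).
    Idempotent. Raises :class:`NameNormalizationError` on empty or
    whitespace-only input.
    """
    if raw is None or not raw.strip():
        raise NameNormalizationError("metabolite name is empty or whitespace-only")
    s = raw.translate(_TRANSLATION).lower().strip()
    return _WS_RUN.sub(" ", s)


@dataclass
class MetaboliteRecord:
    hmdb_id: str
    canonical_name: str
    kegg_id: str | None = None
    pubchem_cid: str | None = None
    metlin_id: str | None = None
    synonyms: list[str] = field(default_factory=list)


@dataclass
class MetaboliteDatabase:
    """Metabolite records plus normalized-name lookup indices.

    ``name_index`` maps normalized canonical names to HMDB accessions;
    ``synonym_index`` maps normalized synonyms to *sets* of accessions —
    a synonym shared by several metabolites is genuinely ambiguous and the
    database keeps that ambiguity (resolution policy lives in the mapper).
    ``accession_index`` lets raw HMDB/KEGG/PubChem/METLIN tokens pass through.
    """

    records: dict[str, MetaboliteRecord]
    name_index: dict[str, str]
    synonym_index: dict[str, set[str]]
    accession_index: dict[str, str]
    version: str = "unversioned"

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PathwayRecord:
    pathway_id: str
    pathway_name: str
    members: set[str]


@dataclass
class PathwayDatabase:
    pathways: dict[str, PathwayRecord]
    version: str = "unversioned"

    def __len__(self) -> int:
        return len(self.pathways)

    def sorted_records(self) -> list[PathwayRecord]:
        return [self.pathways[k] for k in sorted(self.pathways)]


def _read_tsv(path, required_columns: list[str]) -> tuple[pd.DataFrame, str | None]:
    version = None
    with open(path, "rt", encoding="utf-8") as fh:
        lines = []
        for ln in fh:
            if ln.startswith("#"):
                if ln[1:].strip().startswith("version:"):
                    version = ln.split("version:", 1)[1].strip()
                continue
            lines.append(ln)
    from io import StringIO

    try:
        frame = pd.read_csv(StringIO("".join(lines)), sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed TSV
        raise DatabaseFormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required_columns if c not in frame.columns]
    if missing:
        raise DatabaseFormatError(f"{path}: missing required columns {missing}")
    return frame, version


def build_metabolite_db(records: list[MetaboliteRecord], version: str = "unversioned") -> MetaboliteDatabase:
    """Index a record list into a queryable database; validates invariants."""
    by_id: dict[str, MetaboliteRecord] = {}
    name_index: dict[str, str] = {}
    synonym_index: dict[str, set[str]] = {}
    accession_index: dict[str, str] = {}
    for rec in records:
        if not rec.hmdb_id:
            raise DatabaseFormatError("record with empty hmdb_id")
        if rec.hmdb_id in by_id:
            raise DatabaseFormatError(f"duplicate hmdb_id {rec.hmdb_id}")
        if not rec.canonical_name:
            raise DatabaseFormatError(f"{rec.hmdb_id}: empty canonical_name")
        if any(not s for s in rec.synonyms):
            raise DatabaseFormatError(f"{rec.hmdb_id}: empty synonym string")
        by_id[rec.hmdb_id] = rec
        norm = normalize_name(rec.canonical_name)
        prev = name_index.get(norm)
        if prev is not None and prev != rec.hmdb_id:
            keep = min(prev, rec.hmdb_id)
            logger.warning("canonical name %r shared by %s and %s; index keeps %s", norm, prev, rec.hmdb_id, keep)
            name_index[norm] = keep
        else:
            name_index[norm] = rec.hmdb_id
        for syn in rec.synonyms:
            synonym_index.setdefault(normalize_name(syn), set()).add(rec.hmdb_id)
        accession_index[rec.hmdb_id.upper()] = rec.hmdb_id
        for token in (rec.kegg_id, rec.pubchem_cid, rec.metlin_id):
            if token:
                accession_index.setdefault(token.upper(), rec.hmdb_id)
    return MetaboliteDatabase(
        records=by_id,
        name_index=name_index,
        synonym_index=synonym_index,
        accession_index=accession_index,
        version=version,
    )


def load_metabolite_db(path, version: str | None = None) -> MetaboliteDatabase:
    """Load a metabolite snapshot TSV (columns: hmdb_id, canonical_name,
    kegg_id, pubchem_cid, metlin_id, synonyms pipe-separated)."""
    frame, file_version = _read_tsv(path, METABOLITE_COLUMNS)
    records = []
    for line_no, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            records.append(
                MetaboliteRecord(
                    hmdb_id=row.hmdb_id.strip(),
                    canonical_name=row.canonical_name.strip(),
                    kegg_id=row.kegg_id.strip() or None,
                    pubchem_cid=row.pubchem_cid.strip() or None,
                    metlin_id=row.metlin_id.strip() or None,
                    synonyms=[s for s in row.synonyms.split("|") if s],
                )
            )
        except (AttributeError, NameNormalizationError) as exc:
            raise DatabaseFormatError(f"{path}, line {line_no}: {exc}") from exc
    try:
        db = build_metabolite_db(records, version=version or file_version or str(path))
    except DatabaseFormatError as exc:
        raise DatabaseFormatError(f"{path}: {exc}") from exc
    n_syn = sum(len(r.synonyms) for r in db.records.values())
    logger.info("loaded metabolite db %s: %d records, %d synonyms", db.version, len(db), n_syn)
    return db


def write_metabolite_db(db: MetaboliteDatabase, path) -> None:
    rows = [
        {
            "hmdb_id": r.hmdb_id,
            "canonical_name": r.canonical_name,
            "kegg_id": r.kegg_id or "",
            "pubchem_cid": r.pubchem_cid or "",
            "metlin_id": r.metlin_id or "",
            "synonyms": "|".join(r.synonyms),
        }
        for r in (db.records[k] for k in sorted(db.records))
    ]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# version: {db.version}\n")
        pd.DataFrame(rows, columns=METABOLITE_COLUMNS).to_csv(fh, sep="\t", index=False)


def build_pathway_db(records: list[PathwayRecord], version: str = "unversioned") -> PathwayDatabase:
    pathways: dict[str, PathwayRecord] = {}
    for rec in records:
        if rec.pathway_id in pathways:
            raise DatabaseFormatError(f"duplicate pathway_id {rec.pathway_id}")
        if not rec.members:
            raise DatabaseFormatError(f"pathway {rec.pathway_id} has no members")
        bad = [m for m in rec.members if not HMDB_ACCESSION_RE.match(m)]
        if bad:
            raise DatabaseFormatError(f"pathway {rec.pathway_id}: invalid HMDB accessions {sorted(bad)}")
        pathways[rec.pathway_id] = rec
    return PathwayDatabase(pathways=pathways, version=version)


def load_pathway_db(path, version: str | None = None) -> PathwayDatabase:
    """Load a pathway-membership snapshot TSV (members pipe-separated)."""
    frame, file_version = _read_tsv(path, PATHWAY_COLUMNS)
    records = []
    for line_no, row in enumerate(frame.itertuples(index=False), start=2):
        members = {m for m in row.members.split("|") if m}
        if not members:
            raise DatabaseFormatError(f"{path}, line {line_no}: pathway {row.pathway_id} has empty member list")
        records.append(PathwayRecord(row.pathway_id.strip(), row.pathway_name.strip(), members))
    try:
        db = build_pathway_db(records, version=version or file_version or str(path))
    except DatabaseFormatError as exc:
        raise DatabaseFormatError(f"{path}: {exc}") from exc
    logger.info("loaded pathway db %s: %d pathways", db.version, len(db))
    return db


def write_pathway_db(db: PathwayDatabase, path) -> None:
    rows = [
        {
            "pathway_id": r.pathway_id,
            "pathway_name": r.pathway_name,
            "members": "|".join(sorted(r.members)),
        }
        for r in db.sorted_records()
    ]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# version: {db.version}\n")
        pd.DataFrame(rows, columns=PATHWAY_COLUMNS).to_csv(fh, sep="\t", index=False)
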