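"""Three-step standardization of metabolite names to HMDB accessions.

Metabolomics tables arrive with heterogeneous naming: vendor names, trivial
names, synonyms, or raw accessions from HMDB/KEGG/PubChem/METLIN. Mapping
proceeds in three tiers, each consuming only what the previous tier left
unmapped:

1. **exact** — normalized name hits the canonical-name index, or the raw
   token is itself a recognized accession;
2. **synonym** — normalized name hits the synonym index (ambiguous synonyms
   resolve to the lexicographically smallest accession, logged);
3. **fuzzy** — the candidate (over all canonical names and synonyms)
   minimizing Levenshtein distance wins iff the length-normalized distance
   ``dist / max(len(a), len(b))`` is at or below ``max_norm_dist``.

Distances are computed on normalized strings so case and punctuation noise
do not dominate. Everything is deterministic: equidistant fuzzy candidates
and ambiguous synonyms tie-break on the smallest HMDB accession (then the
smallest matched string), and every tie is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .db import MetaboliteDatabase, normalize_name
from .errors import InputError, NameNormalizationError

logger = logging.getLogger(__name__)

DEFAULT_MAX_NORM_DIST = 0.2

TIER_EXACT = "exact"
TIER_SYNONYM = "synonym"
TIER_FUZZY = "fuzzy"
TIER_UNMAPPED = "unmapped"


def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character insertions, deletions and
    substitutions transforming ``a`` into ``b`` (dynamic programming,
    two-row rolling table)."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        append = cur.append
        for j, cb in enumerate(b, start=1):
            append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass
class MappingResult:
    input_name: str
    hmdb_id: str | None
    tier: str
    edit_distance: int | None = None
    matched_string: str | None = None


@dataclass
class MappingTable:
    results: list[MappingResult]

    @property
    def n_input(self) -> int:
        return len(self.results)

    @property
    def n_mapped(self) -> int:
        return sum(1 for r in self.results if r.tier != TIER_UNMAPPED)

    def mapped_ids(self) -> dict[str, str]:
        """input_name -> hmdb_id for every mapped result."""
        return {r.input_name: r.hmdb_id for r in self.results if r.hmdb_id is not None}


def _safe_normalize(name: str) -> str | None:
    try:
        return normalize_name(name)
    except NameNormalizationError:
        return None


def map_exact(names: list[str], db: MetaboliteDatabase) -> list[MappingResult]:
    """Tier 1: canonical-name index hit or raw accession passthrough."""
    out = []
    for name in names:
        token = name.strip().upper()
        hit = db.accession_index.get(token)
        if hit is None:
            norm = _safe_normalize(name)
            if norm is not None:
                hit = db.name_index.get(norm)
        if hit is not None:
            out.append(MappingResult(name, hit, TIER_EXACT, matched_string=db.records[hit].canonical_name))
        else:
            out.append(MappingResult(name, None, TIER_UNMAPPED))
    return out


def map_synonym(names: list[str], db: MetaboliteDatabase) -> list[MappingResult]:
    """Tier 2: synonym-index lookup with deterministic ambiguity tie-break."""
    out = []
    for name in names:
        norm = _safe_normalize(name)
        ids = db.synonym_index.get(norm) if norm is not None else None
        if ids:
            chosen = min(ids)
            if len(ids) > 1:
                logger.warning(
                    "synonym %r is ambiguous (%s); resolved to %s", name, sorted(ids), chosen
                )
            out.append(MappingResult(name, chosen, TIER_SYNONYM, matched_string=norm))
        else:
            out.append(MappingResult(name, None, TIER_UNMAPPED))
    return out


def _candidate_pool(db: MetaboliteDatabase) -> list[tuple[str, str]]:
    """Sorted (normalized candidate, hmdb_id) pairs over names and synonyms."""
    pool = {(norm, hid) for norm, hid in db.name_index.items()}
    for norm, ids in db.synonym_index.items():
        for hid in ids:
            pool.add((norm, hid))
    return sorted(pool)


def map_fuzzy(
    names: list[str],
    db: MetaboliteDatabase,
    max_norm_dist: float = DEFAULT_MAX_NORM_DIST,
) -> list[MappingResult]:
    """Tier 3: nearest candidate by Levenshtein distance on normalized strings.

    A candidate wins iff ``dist / max(len(name), len(candidate))`` is at or
    below ``max_norm_dist``; ties break on (hmdb_id, candidate string).
    """
    pool = _candidate_pool(db)
    out = []
    for name in names:
        norm = _safe_normalize(name)
        if norm is None or not pool:
            out.append(MappingResult(name, None, TIER_UNMAPPED))
            continue
        best: tuple[int, str, str] | None = None  # (dist, hmdb_id, candidate)
        for cand, hid in pool:
            # |len difference| lower-bounds the distance: skip hopeless candidates
            if best is not None and abs(len(cand) - len(norm)) > best[0]:
                continue
            d = levenshtein(norm, cand)
            key = (d, hid, cand)
            if best is None or key < best:
                best = key
            elif key[0] == best[0] and key != best:
                logger.debug("fuzzy tie for %r: kept %s over %s", name, best[1:], (hid, cand))
        dist, hid, cand = best
        if dist / max(len(norm), len(cand)) <= max_norm_dist:
            out.append(MappingResult(name, hid, TIER_FUZZY, edit_distance=dist, matched_string=cand))
        else:
            out.append(MappingResult(name, None, TIER_UNMAPPED))
    return out


def map_features(
    names: list[str],
    db: MetaboliteDatabase,
    max_norm_dist: float = DEFAULT_MAX_NORM_DIST,
) -> MappingTable:
    """Run exact → synonym → fuzzy over the residual unmapped set.

    Duplicate input names are resolved once and broadcast, so identical
    inputs always receive identical results. Input order is preserved.
    """
    if not names:
        raise InputError("no metabolite names supplied")
    unique = list(dict.fromkeys(names))
    resolved: dict[str, MappingResult] = {}

    pending = unique
    for step in (map_exact, map_synonym):
        results = step(pending, db)
        nxt = []
        for name, res in zip(pending, results):
            if res.tier == TIER_UNMAPPED:
                nxt.append(name)
            else:
                resolved[name] = res
        pending = nxt
        if not pending:
            break
    if pending:
        for name, res in zip(pending, map_fuzzy(pending, db, max_norm_dist)):
            resolved[name] = res

    table = MappingTable(results=[resolved[name] for name in names])
    logger.info("mapped %d of %d metabolite names", table.n_mapped, table.n_input)
    return table
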