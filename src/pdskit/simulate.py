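"""Seeded synthetic metabolomics datasets with known ground truth.

Every pipeline stage is testable offline: this module generates miniature
metabolite/pathway reference databases with HMDB-style accessions and
synonyms, two-class intensity matrices with pathway-level deregulation
planted in known pathways, and clinical covariate tables with optional
confounding.

The intensity model is log-normal (log-scale baseline mean 10, between-
metabolite sd 1) to mimic the positivity and right skew of metabolomics
dynamic range. Deregulation is applied on the log scale: member metabolites
of a deregulated pathway have their case-sample log-mean shifted by
``effect_size`` times the per-sample noise sd, i.e. effect_size is a
standardized (Cohen's d) effect on the log scale. Missingness is injected
completely at random. Optional metabolite-name corruption (synonym swap or
k-edit typos) exercises the mapper tiers.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .db import (
    MetaboliteDatabase,
    MetaboliteRecord,
    PathwayDatabase,
    PathwayRecord,
    build_metabolite_db,
    build_pathway_db,
)
from .errors import InputError
from .mapping import levenshtein
from .pds import MetaboliteProfile

logger = logging.getLogger(__name__)

CONTROL_LABEL = "control"
CASE_LABEL = "case"

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"


def _coin_name(rng: np.random.Generator, n_syllables: int = 3) -> str:
    return "".join(rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS)) for _ in range(n_syllables))


def _unique_names(rng: np.random.Generator, n: int, prefix: str = "") -> list[str]:
    names: list[str] = []
    seen = set()
    while len(names) < n:
        name = prefix + _coin_name(rng, int(rng.integers(3, 6)))
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def generate_toy_db(
    n_metabolites: int = 20,
    n_pathways: int = 5,
    members_per_pathway: int = 4,
    synonyms_per_metabolite: int = 2,
    seed: int = 0,
    allow_overlap: bool = True,
) -> tuple[MetaboliteDatabase, PathwayDatabase]:
    """Deterministic miniature reference databases.

    HMDB-style accessions HMDB90xxxxx (synthetic range), pronounceable
    canonical names and synonyms, and pathways drawing members from the
    metabolite pool. With ``allow_overlap=False`` memberships are disjoint
    (requires enough metabolites), so planted deregulation of one pathway
    cannot bleed into another — the setting used for recovery experiments
    with well-defined ground truth.
    """
    if members_per_pathway < 3:
        raise InputError("members_per_pathway must be >= 3 for PDS-eligible pathways")
    if members_per_pathway > n_metabolites:
        raise InputError("members_per_pathway cannot exceed n_metabolites")
    if not allow_overlap and n_pathways * members_per_pathway > n_metabolites:
        raise InputError("disjoint memberships need n_pathways * members_per_pathway <= n_metabolites")
    rng = np.random.default_rng(seed)
    names = _unique_names(rng, n_metabolites)
    records = []
    for i, name in enumerate(names, start=1):
        syns = [f"{name} {suffix}" for suffix in _unique_names(rng, synonyms_per_metabolite)]
        records.append(
            MetaboliteRecord(
                hmdb_id=f"HMDB9{i:06d}",
                canonical_name=name,
                kegg_id=f"C9{i:04d}",
                pubchem_cid=str(900000 + i),
                metlin_id=str(70000 + i),
                synonyms=syns,
            )
        )
    met_db = build_metabolite_db(records, version=f"toy-met-seed{seed}")
    ids = [r.hmdb_id for r in records]
    pathways = []
    if allow_overlap:
        member_sets = [set(rng.choice(ids, size=members_per_pathway, replace=False)) for _ in range(n_pathways)]
    else:
        perm = list(rng.permutation(ids))
        member_sets = [
            set(perm[j * members_per_pathway : (j + 1) * members_per_pathway]) for j in range(n_pathways)
        ]
    for j, members in enumerate(member_sets, start=1):
        pathways.append(PathwayRecord(f"PW{j:04d}", f"pathway {_coin_name(rng, 3)}", members))
    path_db = build_pathway_db(pathways, version=f"toy-path-seed{seed}")
    return met_db, path_db


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic two-class metabolomics experiment."""

    n_cases: int = 60
    n_controls: int = 60
    n_metabolites: int = 80
    pathway_db: PathwayDatabase | None = None
    deregulated_pathways: list[str] = field(default_factory=list)
    effect_size: float = 2.5       # SD units added to case log-means of members
    noise_sd: float = 1.0          # per-sample log-scale noise
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 1.0   # between-metabolite spread of log-means
    missing_rate: float = 0.0
    name_corruption: str = "none"  # none | synonym_swap | typo_k_edits
    typo_edits: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise InputError("effect_size must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise InputError("missing_rate must be in [0, 1)")
        if self.pathway_db is not None:
            unknown = set(self.deregulated_pathways) - set(self.pathway_db.pathways)
            if unknown:
                raise InputError(f"deregulated pathways not in pathway_db: {sorted(unknown)}")


def _apply_typos(name: str, k: int, rng: np.random.Generator) -> str:
    """k random single-character edits at exact Levenshtein distance k."""
    alphabet = string.ascii_lowercase
    for _ in range(50):
        s = name
        for _ in range(k):
            op = rng.integers(0, 3)
            pos = int(rng.integers(0, max(len(s), 1)))
            if op == 0 and len(s) > 1:      # deletion
                s = s[:pos] + s[pos + 1:]
            elif op == 1:                    # insertion
                s = s[:pos] + rng.choice(list(alphabet)) + s[pos:]
            else:                            # substitution
                if not s:
                    continue
                old = s[pos % len(s)]
                new = rng.choice([c for c in alphabet if c != old])
                s = s[: pos % len(s)] + new + s[pos % len(s) + 1:]
        if s != name and levenshtein(s, name) == k:
            return s
    raise RuntimeError(f"could not corrupt {name!r} at distance {k}")


def generate_profile(
    config: SimulationConfig,
    metabolite_db: MetaboliteDatabase | None = None,
) -> tuple[MetaboliteProfile, dict]:
    """Two-class intensity matrix with planted pathway deregulation.

    Returns the profile plus a ground-truth record sufficient to recompute
    every expected property: deregulated pathways, perturbed metabolites,
    the case sample ids and (under name corruption) the corrupted→original
    name map.
    """
    rng = np.random.default_rng(config.seed)
    pathway_members: set[str] = set()
    if config.pathway_db is not None:
        for rec in config.pathway_db.sorted_records():
            pathway_members |= rec.members
    metabolites = sorted(pathway_members)
    n_extra = config.n_metabolites - len(metabolites)
    if n_extra < 0:
        logger.warning("pathway members (%d) exceed n_metabolites (%d); keeping all members", len(metabolites), config.n_metabolites)
    metabolites = metabolites + [f"HMDB8{i:06d}" for i in range(1, max(n_extra, 0) + 1)]

    perturbed: set[str] = set()
    if config.pathway_db is not None:
        for pid in config.deregulated_pathways:
            perturbed |= config.pathway_db.pathways[pid].members

    samples = [f"case_{i:03d}" for i in range(1, config.n_cases + 1)] + [
        f"ctrl_{i:03d}" for i in range(1, config.n_controls + 1)
    ]
    labels = [CASE_LABEL] * config.n_cases + [CONTROL_LABEL] * config.n_controls
    is_case = np.array([lab == CASE_LABEL for lab in labels])

    m, n = len(metabolites), len(samples)
    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=m)
    log_x = base[:, None] + rng.normal(0.0, config.noise_sd, size=(m, n))
    shift = config.effect_size * config.noise_sd
    for i, met in enumerate(metabolites):
        if met in perturbed:
            log_x[i, is_case] += shift
    intensities = pd.DataFrame(np.exp(log_x), index=metabolites, columns=samples)

    if config.missing_rate > 0:
        mask = rng.random(size=(m, n)) < config.missing_rate
        intensities = intensities.mask(pd.DataFrame(mask, index=metabolites, columns=samples))

    name_map: dict[str, str] = {}
    if config.name_corruption != "none":
        if metabolite_db is None:
            raise InputError("name corruption requires a metabolite database")
        new_index = []
        for met in metabolites:
            rec = metabolite_db.records.get(met)
            if rec is None:
                new_index.append(met)
                continue
            if config.name_corruption == "synonym_swap":
                corrupted = str(rng.choice(sorted(rec.synonyms))) if rec.synonyms else rec.canonical_name
            elif config.name_corruption == "typo_k_edits":
                corrupted = _apply_typos(rec.canonical_name, config.typo_edits, rng)
            else:
                raise InputError(f"unknown name_corruption {config.name_corruption!r}")
            name_map[corrupted] = met
            new_index.append(corrupted)
        intensities.index = new_index

    profile = MetaboliteProfile(
        intensities=intensities,
        phenotype=pd.Series(labels, index=samples),
        control_label=CONTROL_LABEL,
    )
    truth = {
        "deregulated_pathways": sorted(config.deregulated_pathways),
        "perturbed_metabolites": sorted(perturbed),
        "case_samples": [s for s, lab in zip(samples, labels) if lab == CASE_LABEL],
        "effect_size": config.effect_size,
        "noise_sd": config.noise_sd,
        "name_map": name_map,
        "seed": config.seed,
    }
    return profile, truth


def generate_pds_like(
    n_cases: int,
    n_controls: int,
    n_features: int,
    informative: list[str] | int,
    effect: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Synthetic pathway×sample score matrix with planted informative rows.

    Scores mimic PDS output: values squashed into [0, 1] by the logistic
    function of a Gaussian, with the case mean of informative rows shifted by
    ``effect`` SD. Returns (scores, 0/1 labels, informative row ids).
    """
    rng = np.random.default_rng(seed)
    ids = [f"PW{i:04d}" for i in range(1, n_features + 1)]
    if isinstance(informative, int):
        informative = list(rng.choice(ids, size=informative, replace=False))
    informative = sorted(informative)
    y = np.array([1] * n_cases + [0] * n_controls)
    samples = [f"s{i:03d}" for i in range(1, len(y) + 1)]
    Z = rng.normal(0.0, 1.0, size=(n_features, len(y)))
    for i, pid in enumerate(ids):
        if pid in informative:
            Z[i, y == 1] += effect
    scores = pd.DataFrame(1.0 / (1.0 + np.exp(-Z)), index=ids, columns=samples)
    return scores, y, informative


def generate_clinical(labels, confounded: bool = False, seed: int = 0, age_shift: float = 10.0) -> pd.DataFrame:
    """Clinical covariate table: age (years), sex and ethnicity.

    With ``confounded=True`` the case-sample age mean is shifted by
    ``age_shift`` years (sd 8), making age a genuine confounder.
    """
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    age = rng.normal(55.0, 8.0, size=n)
    if confounded:
        age = age + age_shift * (labels != CONTROL_LABEL).to_numpy(dtype=float)
    sex = rng.choice(["F", "M"], size=n)
    ethnicity = rng.choice(["groupA", "groupB", "groupC", "groupD"], size=n)
    return pd.DataFrame({"age": age, "sex": sex, "ethnicity": ethnicity}, index=labels.index)
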