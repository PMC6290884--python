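"""Phenotype-relevant pathway selection by information gain / gain ratio.

Pathway deregulation scores are continuous, so each pathway's score vector is
first discretized by recursive entropy-minimizing binary splits with the
Fayyad–Irani minimum-description-length (MDL) stopping rule: a split is kept
only when the information it adds outweighs the cost of describing it, which
zeroes out uninformative features and keeps selected sets small. Information
gain is the drop in class-label entropy from conditioning on the bins; gain
ratio divides by the entropy of the bin-membership distribution, penalizing
many-valued splits. For a binary phenotype both scores live in [0, 1] bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def entropy(labels) -> float:
    """Shannon entropy in bits; 0·log 0 taken as 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass
class DiscretizationScheme:
    cut_points: list[float]
    method: str = "mdl"

    def bin_of(self, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(np.asarray(self.cut_points), np.asarray(values), side="right")


def _class_counts(codes: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(codes, minlength=n_classes)


def _ent_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _best_split(values: np.ndarray, codes: np.ndarray, n_classes: int):
    """Entropy-minimizing binary cut over midpoints between distinct values.

    Returns (cut, gain, left_counts, right_counts) or None when no candidate
    cut exists."""
    order = np.argsort(values, kind="stable")
    v, c = values[order], codes[order]
    n = len(v)
    boundaries = np.nonzero(np.diff(v) > 0)[0]  # split after index i
    if boundaries.size == 0:
        return None
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), c] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    H = _ent_from_counts(total.astype(int))
    best = None
    for i in boundaries:
        left = cum[i]
        right = total - left
        nl = i + 1
        nr = n - nl
        cond = (nl * _ent_from_counts(left.astype(int)) + nr * _ent_from_counts(right.astype(int))) / n
        gain = H - cond
        cut = (v[i] + v[i + 1]) / 2.0
        if best is None or gain > best[1] + 1e-12:
            best = (cut, gain, left.astype(int), right.astype(int))
    return best


def _mdl_accepts(n: int, gain: float, total: np.ndarray, left: np.ndarray, right: np.ndarray) -> bool:
    """Fayyad–Irani MDL criterion for accepting a binary split."""
    k = int((total > 0).sum())
    k1 = int((left > 0).sum())
    k2 = int((right > 0).sum())
    ent, ent1, ent2 = _ent_from_counts(total), _ent_from_counts(left), _ent_from_counts(right)
    delta = np.log2(3.0**k - 2.0) - (k * ent - k1 * ent1 - k2 * ent2)
    threshold = (np.log2(n - 1) + delta) / n
    return gain > threshold


def discretize_mdl(values, labels) -> DiscretizationScheme:
    """Recursive MDL-stopped binary discretization of a continuous feature.

    Returns possibly empty cut points; an empty scheme marks the feature as
    unsplittable (score 0 downstream).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0] or values.shape[0] < 2:
        raise ValueError("values and labels must have equal length >= 2")
    classes, codes = np.unique(labels, return_inverse=True)
    cuts: list[float] = []

    def recurse(mask: np.ndarray) -> None:
        v, c = values[mask], codes[mask]
        n = len(v)
        if n < 2:
            return
        split = _best_split(v, c, len(classes))
        if split is None:
            return
        cut, gain, left_counts, right_counts = split
        if not _mdl_accepts(n, gain, left_counts + right_counts, left_counts, right_counts):
            return
        cuts.append(cut)
        recurse(mask & (values <= cut))
        recurse(mask & (values > cut))

    recurse(np.ones(len(values), dtype=bool))
    return DiscretizationScheme(cut_points=sorted(cuts), method="mdl")


def discretize_equal_frequency(values, n_bins: int | None = None) -> DiscretizationScheme:
    """Fallback scheme: ⌈√n⌉ equal-frequency bins (label-agnostic)."""
    values = np.asarray(values, dtype=float)
    n_bins = n_bins or int(np.ceil(np.sqrt(len(values))))
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    cuts = sorted(set(float(q) for q in qs if values.min() < q < values.max()))
    return DiscretizationScheme(cut_points=cuts, method="equal_frequency")


def information_gain(values, labels, scheme: DiscretizationScheme) -> float:
    """H(labels) − Σ_bins (n_bin/n)·H(labels | bin); empty scheme ⇒ 0."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if not scheme.cut_points:
        return 0.0
    H = entropy(labels)
    bins = scheme.bin_of(values)
    n = len(values)
    cond = 0.0
    for b in np.unique(bins):
        in_bin = bins == b
        cond += in_bin.sum() / n * entropy(labels[in_bin])
    return float(max(0.0, H - cond))


def gain_ratio(values, labels, scheme: DiscretizationScheme) -> float:
    """Information gain divided by the bin-membership entropy (intrinsic
    value); 0 when the intrinsic value is 0."""
    ig = information_gain(values, labels, scheme)
    if ig == 0.0:
        return 0.0
    bins = scheme.bin_of(np.asarray(values, dtype=float))
    iv = entropy(bins)
    if iv <= 0.0:
        return 0.0
    return float(ig / iv)


@dataclass
class RankedFeature:
    pathway_id: str
    score: float
    method: str
    selected: bool


@dataclass
class FeatureRanking:
    entries: list[RankedFeature]

    @property
    def selected_ids(self) -> list[str]:
        return [e.pathway_id for e in self.entries if e.selected]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pathway_id": e.pathway_id, "score": e.score, "selected": int(e.selected), "method": e.method}
                for e in self.entries
            ]
        )


def select_features(
    pds_scores: pd.DataFrame,
    labels,
    method: str = "infogain",
    top_k: int | None = 20,
) -> FeatureRanking:
    """Score every pathway's PDS vector against the phenotype and select.

    ``pds_scores`` is pathways × samples. Features with score > 0 are
    selected, capped at ``top_k`` (ties broken by pathway_id). Scores are in
    bits; for a binary phenotype they lie in [0, 1].
    """
    if method not in ("infogain", "gainratio"):
        raise ValueError(f"unknown selection method {method!r}")
    labels = np.asarray(labels)
    scorer = information_gain if method == "infogain" else gain_ratio
    scored = []
    for pid in pds_scores.index:
        v = pds_scores.loc[pid].to_numpy(dtype=float)
        scheme = discretize_mdl(v, labels)
        scored.append((pid, float(scorer(v, labels, scheme))))
    scored.sort(key=lambda t: (-t[1], t[0]))
    cap = top_k if top_k is not None else len(scored)
    entries = [
        RankedFeature(pid, score, method, selected=(score > 0.0 and rank < cap))
        for rank, (pid, score) in enumerate(scored)
    ]
    n_sel = sum(e.selected for e in entries)
    if n_sel == 0:
        logger.warning("no pathway achieved a positive %s score; empty selection", method)
    else:
        logger.info("selected %d of %d pathways by %s", n_sel, len(entries), method)
    return FeatureRanking(entries=entries)
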