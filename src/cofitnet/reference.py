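"""Reference labels for classifier training.

Positives are gene pairs supported by at least ``min_support`` of the
curated studies.  Among the remaining pairs, a pair is a negative when the
two genes share no annotation term (the ontology root does not count as an
annotation — it would make every pair share a term); everything else stays
unlabeled and is excluded from training.  Positivity takes precedence over
the annotation rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "UNLABELED",
    "ReferenceLabels",
    "build_positives",
    "build_negatives",
    "assemble_training_table",
]

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
UNLABELED = "UNLABELED"

ROOT_TERM = "T:ROOT"


@dataclass
class ReferenceLabels:
    """pair -> label over a fixed pair universe; labels partition the universe."""

    labels: dict[frozenset[str], str]

    def counts(self) -> dict[str, int]:
        c = Counter(self.labels.values())
        return {POSITIVE: c[POSITIVE], NEGATIVE: c[NEGATIVE], UNLABELED: c[UNLABELED]}

    def pairs_with(self, label: str) -> set[frozenset[str]]:
        return {p for p, l in self.labels.items() if l == label}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            ((min(p), max(p), l) for p, l in self.labels.items()),
            key=lambda r: (r[0], r[1]),
        )
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"])


def build_positives(
    studies: list[set[frozenset[str]]], min_support: int = 2
) -> set[frozenset[str]]:
    """Pairs reported by at least ``min_support`` studies (order-insensitive)."""
    if min_support > len(studies):
        raise ValueError(
            f"min_support={min_support} exceeds number of studies ({len(studies)})"
        )
    support: Counter[frozenset[str]] = Counter()
    for study in studies:
        for pair in study:
            if len(pair) != 2:
                raise ValueError(f"malformed pair {set(pair)}")
            support[pair] += 1
    return {p for p, c in support.items() if c >= min_support}


def build_negatives(
    pair_universe: set[frozenset[str]],
    positives: set[frozenset[str]],
    annotations: dict[str, set[str]],
    root_term: str = ROOT_TERM,
) -> ReferenceLabels:
    """Label every pair of the universe POSITIVE / NEGATIVE / UNLABELED."""
    stray = positives - pair_universe
    if stray:
        raise ValueError(
            f"{len(stray)} positive pairs lie outside the pair universe, "
            f"e.g. {sorted(next(iter(stray)))}"
        )
    labels: dict[frozenset[str], str] = {}
    for pair in pair_universe:
        if pair in positives:
            labels[pair] = POSITIVE
            continue
        a, b = sorted(pair)
        terms_a = annotations.get(a, set()) - {root_term}
        terms_b = annotations.get(b, set()) - {root_term}
        labels[pair] = NEGATIVE if terms_a.isdisjoint(terms_b) else UNLABELED
    return ReferenceLabels(labels)


@dataclass
class TrainingTable:
    """Labelled, class-balanced, z-scored feature rows ready for model fits.

    ``feature_means`` / ``feature_sds`` are the training-set statistics and
    must be reused verbatim when scoring the full pair universe.
    """

    X: np.ndarray  # (n_rows, n_features), z-scored
    y: np.ndarray  # (n_rows,), 1 = positive
    pairs: list[frozenset[str]]
    feature_names: tuple[str, ...]
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Apply the stored z-scoring to raw feature rows."""
        return (raw - self.feature_means) / self.feature_sds


def assemble_training_table(
    features: pd.DataFrame,
    labels: ReferenceLabels,
    neg_pos_ratio: float | None = 5.0,
    seed: int = 0,
) -> TrainingTable:
    """Keep all positives, downsample negatives to ``neg_pos_ratio`` x, z-score.

    ``neg_pos_ratio=None`` keeps every negative.  UNLABELED pairs never enter
    the table.  The negative subsample is drawn without replacement with a
    seeded generator, so the same seed reproduces the same row set.
    """
    key = [frozenset((a, b)) for a, b in zip(features["gene_a"], features["gene_b"])]
    lab = np.array([labels.labels.get(p, UNLABELED) for p in key])
    pos_idx = np.flatnonzero(lab == POSITIVE)
    neg_idx = np.flatnonzero(lab == NEGATIVE)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError(
            f"need both classes among feature rows; got {len(pos_idx)} positives "
            f"and {len(neg_idx)} negatives"
        )
    if neg_pos_ratio is not None:
        n_neg = min(len(neg_idx), int(round(neg_pos_ratio * len(pos_idx))))
        rng = np.random.default_rng(seed)
        neg_idx = np.sort(rng.choice(neg_idx, size=n_neg, replace=False))
    keep = np.concatenate([pos_idx, neg_idx])

    raw = features.iloc[keep][list(FEATURE_NAMES)].to_numpy(dtype=float)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)  # constant feature stays constant at 0
    X = (raw - means) / sds
    y = (lab[keep] == POSITIVE).astype(np.int64)
    return TrainingTable(
        X=X,
        y=y,
        pairs=[key[i] for i in keep],
        feature_names=FEATURE_NAMES,
        feature_means=means,
        feature_sds=sds,
    )
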