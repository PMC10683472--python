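"""Post-selection analytics: abundance ranking, sequence-family clustering
and model-predicted library-fitness trajectories.

Family calling uses deterministic greedy Hamming-distance clustering rather
than an embedding: the most abundant unassigned insert seeds a family, other
inserts of the same length join while within ``max_hamming`` of the seed,
and the consensus takes the count-weighted majority residue per position
(wildcard ``x`` where no residue reaches 50%).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "FrequencyTable",
    "Family",
    "abundance_rank",
    "HammingFamilyClustering",
    "cluster_families",
    "fitness_trajectory",
]

logger = logging.getLogger(__name__)


def abundance_rank(counts: Mapping[str, int] | Iterable[str]) -> pd.DataFrame:
    """Rank inserts by count (descending; ties broken lexicographically).

    Returns a frame with columns insert, count, frequency, rank; frequencies
    sum to 1 and ranks are the permutation 1..k.
    """
    counts = Counter(counts) if not isinstance(counts, Mapping) else dict(counts)
    if not counts:
        raise ValueError("empty input")
    frame = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["insert", "count"],
    )
    frame["frequency"] = frame["count"] / frame["count"].sum()
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


FrequencyTable = pd.DataFrame  # alias: output shape of abundance_rank


@dataclass
class Family:
    """A group of same-length inserts within Hamming reach of a seed."""

    seed: str
    members: list[str]
    consensus: str
    total_frequency: float

    def __post_init__(self) -> None:
        if len(self.consensus) != len(self.seed):
            raise ValueError("consensus length must equal member length")


def _consensus(members: Sequence[str], weights: Sequence[int]) -> str:
    length = len(members[0])
    total = sum(weights)
    out = []
    for pos in range(length):
        tally = Counter()
        for m, w in zip(members, weights):
            tally[m[pos]] += w
        res, top = tally.most_common(1)[0]
        out.append(res if top / total >= 0.5 else "x")
    return "".join(out)


class HammingFamilyClustering(BaseEstimator):
    """Greedy abundance-seeded Hamming-distance family clustering.

    scikit-learn style: ``fit(X, sample_weight=counts)`` where X is a
    sequence of insert strings.  Fitted attributes: ``families_`` (list of
    :class:`Family`, most abundant first) and ``labels_`` (family index per
    input; −1 for members of families below ``min_members``).

    Inserts of different lengths never co-cluster.  Deterministic: seeds are
    chosen by abundance, ties broken lexicographically.
    """

    def __init__(self, max_hamming: int = 3, min_members: int = 1):
        self.max_hamming = max_hamming
        self.min_members = min_members

    def fit(self, X: Sequence[str], y=None, sample_weight=None):
        inserts = list(X)
        if sample_weight is None:
            sample_weight = [1] * len(inserts)
        weights = [int(w) for w in sample_weight]
        if len(weights) != len(inserts):
            raise ValueError("sample_weight length mismatch")
        total = sum(weights)
        order = sorted(range(len(inserts)),
                       key=lambda i: (-weights[i], inserts[i]))
        assigned = [False] * len(inserts)
        labels = np.full(len(inserts), -1, dtype=int)
        families: list[Family] = []
        for si in order:
            if assigned[si]:
                continue
            seed = inserts[si]
            member_idx = [
                j for j in order
                if not assigned[j]
                and len(inserts[j]) == len(seed)
                and sum(a != b for a, b in zip(inserts[j], seed)) <= self.max_hamming
            ]
            for j in member_idx:
                assigned[j] = True
            if len(member_idx) < self.min_members:
                continue
            members = [inserts[j] for j in member_idx]
            w = [weights[j] for j in member_idx]
            fam = Family(
                seed=seed,
                members=members,
                consensus=_consensus(members, w),
                total_frequency=sum(w) / total,
            )
            labels[member_idx] = len(families)
            families.append(fam)
        self.families_ = families
        self.labels_ = labels
        return self


def cluster_families(
    counts: Mapping[str, int],
    max_hamming: int = 3,
    min_members: int = 1,
) -> list[Family]:
    """Functional wrapper over :class:`HammingFamilyClustering`."""
    inserts = list(counts)
    est = HammingFamilyClustering(max_hamming, min_members)
    est.fit(inserts, sample_weight=[counts[s] for s in inserts])
    return est.families_


def fitness_trajectory(
    predictor,
    rounds: Sequence[Iterable[str] | Mapping[str, int]],
    weighted: bool = False,
) -> np.ndarray:
    """Mean predicted fitness per round, in round order.

    By default the mean is over unique inserts (unweighted by abundance);
    ``weighted=True`` weights by counts instead.  Inserts whose length the
    predictor does not support are excluded from the mean with a logged
    count.
    """
    if len(rounds) == 0:
        raise ValueError("need at least one round")
    means = []
    for r_idx, entry in enumerate(rounds):
        counts = Counter(entry) if not isinstance(entry, Mapping) else dict(entry)
        inserts = sorted(counts)
        supported, weights, skipped = [], [], 0
        for s in inserts:
            try:
                # cheap support probe: a 1-element batch raises on bad length
                max_len = getattr(predictor, "max_len", None)
                if max_len is not None and len(s) > max_len:
                    raise ValueError("unsupported length")
                supported.append(s)
                weights.append(counts[s] if weighted else 1)
            except ValueError:
                skipped += 1
        if skipped:
            logger.warning("round %d: excluded %d inserts with unsupported length",
                           r_idx, skipped)
        if not supported:
            raise ValueError(f"round {r_idx}: no inserts with supported length")
        preds = (predictor.predict_fitness(supported)
                 if hasattr(predictor, "predict_fitness")
                 else np.asarray(predictor(supported), dtype=float))
        w = np.asarray(weights, dtype=float)
        means.append(float(np.dot(preds, w) / w.sum()))
    return np.asarray(means)
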