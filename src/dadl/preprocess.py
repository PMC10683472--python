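"""Turn raw selection/antiselection FASTQ reads into labeled peptide datasets.

Pipeline: quality filtering (any base below the Phred threshold discards the
read), in-silico translation anchored at the constant core flanks, rejection
of truncated / mutated / stop-containing reads, deduplication with count
aggregation, removal of inserts seen in both the selection and antiselection
pools, binary labeling (1 = selection, 0 = antiselection) and a seeded
train/validation/test split.

All stages are deterministic given the input files and the seed; rejected
reads are tallied by reason rather than raised.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .codons import AA_ALPHABET, LibraryDesign, PrecursorTemplate

__all__ = [
    "ReadRecord",
    "PeptideRecord",
    "LabeledDataset",
    "FastqFormatError",
    "read_fastq",
    "quality_filter",
    "translate_and_validate",
    "collapse_reads",
    "build_labeled_dataset",
]


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ input, with the approximate line number."""


@dataclass
class ReadRecord:
    identifier: str
    dna: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.dna):
            raise ValueError(
                f"read {self.identifier}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.dna)}"
            )


@dataclass
class PeptideRecord:
    insert: str
    count: int = 1
    label: int | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if "*" in self.insert:
            raise ValueError("insert contains a stop symbol")


def read_fastq(path) -> Iterator[ReadRecord]:
    """Lazily yield reads from a Phred+33 FASTQ file.

    Malformed records raise :class:`FastqFormatError` carrying the
    approximate line number (4 lines per record).
    """
    n_seen = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n_seen += 1
            yield ReadRecord(
                identifier=rec.id,
                dna=str(rec.seq).upper(),
                quality=tuple(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:
        raise FastqFormatError(
            f"{path}: malformed FASTQ near line {4 * n_seen + 1}: {exc}"
        ) from exc


@dataclass
class FilterStats:
    kept: int = 0
    discarded: int = 0


def quality_filter(
    reads: Iterable[ReadRecord], min_phred: int = 30
) -> tuple[list[ReadRecord], FilterStats]:
    """Discard any read with at least one base call below ``min_phred``."""
    stats = FilterStats()
    kept = []
    for read in reads:
        if min_phred <= 0 or min(read.quality) >= min_phred:
            kept.append(read)
            stats.kept += 1
        else:
            stats.discarded += 1
    return kept, stats


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def translate_and_validate(
    read: ReadRecord,
    design: LibraryDesign,
    mismatch_tolerance: int = 0,
    allowed_lengths: Sequence[int] | None = None,
) -> tuple[str | None, str]:
    """Translate a read and extract its insert, or give the rejection reason.

    The expected layout at the amino-acid level is
    ``core_pre + insert + core_post (+ linker)``.  The read is translated in
    frame 0; the upstream flank anchors the frame and the downstream flank is
    matched at every allowed insert length (best = fewest mismatches, ties
    to the shortest length).

    Returns ``(insert, "ok")`` on success or ``(None, reason)`` with reason
    one of ``"truncated"``, ``"template_mismatch"``, ``"stop_in_insert"``,
    ``"ambiguous_residue"``.
    """
    tpl = design.template
    if allowed_lengths is None:
        allowed_lengths = range(design.length_bounds[0], design.length_bounds[1] + 1)
    prot = str(Seq(read.dna[: 3 * (len(read.dna) // 3)]).translate())
    pre, post = tpl.core_pre, tpl.core_post
    if len(prot) < len(pre) + min(allowed_lengths) + len(post):
        return None, "truncated"
    pre_mm = _mismatches(prot[: len(pre)], pre)

    best = None  # (mismatches, length, insert)
    for length in sorted(allowed_lengths):
        lo = len(pre) + length
        hi = lo + len(post)
        if hi > len(prot):
            break
        mm = _mismatches(prot[lo:hi], post)
        if best is None or mm < best[0]:
            best = (mm, length, prot[len(pre):lo])
    if best is None:
        return None, "truncated"
    post_mm, _length, insert = best
    if pre_mm + post_mm > mismatch_tolerance:
        # frameshifts scramble everything downstream; heavy damage on the
        # downstream flank alone is indistinguishable from truncation
        if post_mm > len(post) // 2 and pre_mm <= mismatch_tolerance:
            return None, "truncated"
        return None, "template_mismatch"
    if "*" in insert:
        return None, "stop_in_insert"
    if any(res not in AA_ALPHABET for res in insert):
        return None, "ambiguous_residue"
    return insert, "ok"


def collapse_reads(
    reads: Iterable[ReadRecord],
    design: LibraryDesign,
    mismatch_tolerance: int = 0,
    source: str | None = None,
) -> tuple[Counter, Counter]:
    """Translate/validate a batch of reads into an insert multiset.

    Returns ``(insert_counts, rejection_tally)``.
    """
    counts: Counter = Counter()
    tally: Counter = Counter()
    for read in reads:
        insert, reason = translate_and_validate(read, design, mismatch_tolerance)
        if insert is None:
            tally[reason] += 1
        else:
            counts[insert] += 1
            tally["ok"] += 1
    return counts, tally


@dataclass
class LabeledDataset:
    """Deduplicated labeled peptides with a seeded train/val/test split.

    ``frame`` columns: insert, count, label, split, source.  No insert
    appears with both labels (the intersection of selection and
    antiselection pools is removed before labeling), and splits are
    disjoint by insert.
    """

    frame: pd.DataFrame
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels_per_insert = self.frame.groupby("insert")["label"].nunique()
        if (labels_per_insert > 1).any():
            raise ValueError("an insert appears with both labels")

    def __len__(self) -> int:
        return len(self.frame)

    def split_frame(self, split: str) -> pd.DataFrame:
        return self.frame[self.frame["split"] == split]

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, seed: int = 0) -> "LabeledDataset":
        return cls(pd.read_csv(path, sep="\t"), seed=seed)


def build_labeled_dataset(
    selection_inserts: Iterable[str] | Counter,
    antiselection_inserts: Iterable[str] | Counter,
    seed: int = 0,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    source: str | None = None,
) -> LabeledDataset:
    """Deduplicate, cross-filter and label the two pools.

    Counts are aggregated per unique insert first; inserts present in both
    pools are discarded from both; survivors get label 1 (selection) or 0
    (antiselection).  The split is a seeded shuffle of unique inserts cut at
    the requested fractions.
    """
    sel = Counter(selection_inserts)
    anti = Counter(antiselection_inserts)
    if not sel or not anti:
        raise ValueError("both selection and antiselection pools must be non-empty")
    shared = set(sel) & set(anti)
    rows = [
        {"insert": s, "count": c, "label": 1}
        for s, c in sel.items() if s not in shared
    ] + [
        {"insert": s, "count": c, "label": 0}
        for s, c in anti.items() if s not in shared
    ]
    if not rows:
        raise ValueError(
            "no peptides left after removing the selection/antiselection overlap"
        )
    frame = pd.DataFrame(rows).sort_values("insert", kind="stable").reset_index(drop=True)
    frame["source"] = source

    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(frame))
    n_train = int(round(split_fractions[0] * len(frame)))
    n_val = int(round(split_fractions[1] * len(frame)))
    split = np.empty(len(frame), dtype=object)
    split[perm[:n_train]] = "train"
    split[perm[n_train:n_train + n_val]] = "val"
    split[perm[n_train + n_val:]] = "test"
    frame["split"] = split
    return LabeledDataset(
        frame,
        seed=seed,
        provenance={
            "n_selection_unique": len(sel),
            "n_antiselection_unique": len(anti),
            "n_shared_removed": len(shared),
            "seed": seed,
        },
    )
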