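"""Exact combinatorics of IUPAC degenerate codons.

A degenerate codon (``nnk``, ``dsk``, ...) is a triplet of IUPAC nucleotide
ambiguity symbols that encodes a defined mixture of concrete codons, and
through the genetic code a weighted set of amino acids.  This module provides
expansion, translation, per-position amino-acid profiles, exact theoretical
diversity of a library design, and seeded peptide sampling.

Conventions
-----------
* Degenerate codons are written lower-case; concrete DNA sequences and
  peptides are upper-case.
* ``u`` is accepted as a synonym of ``t`` (designs are often written
  RNA-style, e.g. ``nnu``).
* Diversity counts distinct stop-free peptide sequences: stop codons are
  excluded, not treated as a 21st letter.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "IUPAC_BASES",
    "DegenerateCodon",
    "PrecursorTemplate",
    "LibraryDesign",
    "AAProfile",
    "expand_codon",
    "codon_amino_acids",
    "design_diversity",
    "design_aa_profile",
    "sample_peptides",
    "parse_design_spec",
]

#: IUPAC nucleotide ambiguity symbols and the base sets they stand for.
IUPAC_BASES: Mapping[str, str] = {
    "a": "A", "c": "C", "g": "G", "t": "T",
    "r": "AG", "y": "CT", "s": "CG", "w": "AT", "k": "GT", "m": "AC",
    "b": "CGT", "d": "AGT", "h": "ACT", "v": "ACG", "n": "ACGT",
}

#: The 20 proteinogenic amino acids, alphabetical one-letter codes.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"


def _normalize_symbol(sym: str) -> str:
    s = sym.lower()
    if s == "u":
        s = "t"
    if s not in IUPAC_BASES:
        raise ValueError(f"invalid IUPAC nucleotide symbol: {sym!r}")
    return s


@dataclass(frozen=True)
class DegenerateCodon:
    """A codon written in IUPAC ambiguity symbols, e.g. ``nnk``.

    Symbols are normalized to lower case with ``u`` mapped to ``t``.
    """

    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) != 3:
            raise ValueError(
                f"a codon needs exactly 3 symbols, got {self.symbols!r}"
            )
        norm = "".join(_normalize_symbol(s) for s in self.symbols)
        object.__setattr__(self, "symbols", norm)

    @property
    def size(self) -> int:
        """Number of concrete codons in the expansion (1..64)."""
        return math.prod(len(IUPAC_BASES[s]) for s in self.symbols)

    def expand(self) -> tuple[str, ...]:
        return expand_codon(self)

    def amino_acids(self) -> tuple[Counter, int]:
        return codon_amino_acids(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbols


def expand_codon(codon: DegenerateCodon | str) -> tuple[str, ...]:
    """Expand a degenerate codon into the sorted tuple of concrete DNA codons.

    The expansion is the Cartesian product of the three per-symbol base sets;
    its size is the product of the set sizes.
    """
    if not isinstance(codon, DegenerateCodon):
        codon = DegenerateCodon(codon)
    sets = [IUPAC_BASES[s] for s in codon.symbols]
    return tuple("".join(bases) for bases in product(*sets))


def codon_amino_acids(codon: DegenerateCodon | str) -> tuple[Counter, int]:
    """Translate every concrete codon in the expansion.

    Returns
    -------
    (aa_multiset, n_stops)
        ``aa_multiset`` maps amino acid -> number of encoding codons in the
        expansion; stop codons are tallied separately in ``n_stops``.
    """
    aa = Counter()
    stops = 0
    for c in expand_codon(codon):
        t = _CODON_TO_AA[c]
        if t == "*":
            stops += 1
        else:
            aa[t] += 1
    return aa, stops


@dataclass(frozen=True)
class PrecursorTemplate:
    """Fixed precursor context around the randomized insert.

    The core region reads ``core_pre + insert + core_post + linker`` at the
    amino-acid level; ``leader`` is the (constant) enzyme-recognition region
    upstream of the core.  Defaults place the insert between the required
    Ser-Trp pair and the required Ser-Ser-Ser-Cys-Ala run, followed by a
    short C-terminal linker.
    """

    leader: str = ""
    core_pre: str = "SW"
    core_post: str = "SSSCA"
    linker: str = "GS"

    def __post_init__(self) -> None:
        for name in ("leader", "core_pre", "core_post", "linker"):
            seq = getattr(self, name)
            bad = set(seq) - set(AA_ALPHABET)
            if bad:
                raise ValueError(
                    f"template {name} contains non-standard residues: {sorted(bad)}"
                )


DEFAULT_TEMPLATE = PrecursorTemplate()


@dataclass(frozen=True)
class LibraryDesign:
    """An ordered list of degenerate codons inside a fixed precursor template."""

    insert_codons: tuple[DegenerateCodon, ...]
    template: PrecursorTemplate = DEFAULT_TEMPLATE
    length_bounds: tuple[int, int] = (6, 12)

    def __post_init__(self) -> None:
        codons = tuple(
            c if isinstance(c, DegenerateCodon) else DegenerateCodon(c)
            for c in self.insert_codons
        )
        object.__setattr__(self, "insert_codons", codons)
        lo, hi = self.length_bounds
        if not lo <= len(codons) <= hi:
            raise ValueError(
                f"insert length {len(codons)} outside configured bounds "
                f"[{lo}, {hi}]"
            )

    def __len__(self) -> int:
        return len(self.insert_codons)

    @property
    def spec(self) -> str:
        """Space-separated codon listing, e.g. ``'dsk nnk ... nnu'``."""
        return " ".join(c.symbols for c in self.insert_codons)

    def replace_codon(self, position: int, codon: DegenerateCodon | str) -> "LibraryDesign":
        """Return a copy with the 1-based insert ``position`` substituted."""
        if not 1 <= position <= len(self):
            raise ValueError(f"position {position} outside insert 1..{len(self)}")
        if not isinstance(codon, DegenerateCodon):
            codon = DegenerateCodon(codon)
        codons = list(self.insert_codons)
        codons[position - 1] = codon
        return LibraryDesign(tuple(codons), self.template, self.length_bounds)


@dataclass
class AAProfile:
    """Per-position amino-acid probabilities of a design (stops excluded)."""

    probs: list[dict[str, float]]
    counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = [len(p) for p in self.probs]

    def __len__(self) -> int:
        return len(self.probs)

    def position(self, i: int) -> dict[str, float]:
        """Probabilities at 1-based insert position ``i``."""
        return self.probs[i - 1]


def _position_weights(codon: DegenerateCodon) -> Counter:
    aa, _stops = codon_amino_acids(codon)
    if not aa:
        raise ValueError(
            f"codon {codon.symbols!r} encodes only stop codons"
        )
    return aa


def design_diversity(design: LibraryDesign) -> int:
    """Count of distinct stop-free peptides the design can encode.

    Exact integer product over insert positions of the number of distinct
    non-stop amino acids encoded at that position.  Fixed template positions
    contribute a factor of 1.
    """
    d = 1
    for codon in design.insert_codons:
        d *= len(_position_weights(codon))
    return d


def design_aa_profile(design: LibraryDesign) -> AAProfile:
    """Per-position amino-acid probabilities, proportional to the number of
    encoding codons among non-stop expansions (e.g. Ser takes 3 of the 31
    stop-free nnk codons)."""
    probs = []
    counts = []
    for codon in design.insert_codons:
        w = _position_weights(codon)
        total = sum(w.values())
        probs.append({a: w[a] / total for a in sorted(w)})
        counts.append(len(w))
    return AAProfile(probs, counts)


def sample_peptides(
    design: LibraryDesign,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw ``n`` i.i.d. insert peptides from the design.

    Per position a concrete codon is drawn uniformly from the expansion and
    translated; stop draws are rejected and redrawn, which is equivalent to
    (and implemented as) a multiplicity-weighted draw over the non-stop
    amino acids.  Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    columns = []
    for codon in design.insert_codons:
        w = _position_weights(codon)
        letters = np.array(sorted(w))
        p = np.array([w[a] for a in sorted(w)], dtype=float)
        p /= p.sum()
        columns.append(letters[rng.choice(len(letters), size=n, p=p)])
    grid = np.stack(columns, axis=1)
    return ["".join(row) for row in grid]


_REPEAT_RE = re.compile(r"^\((?P<codon>[a-zA-Z]{3})\)_?(?P<n>\d+)$")


def parse_design_spec(
    spec: str,
    template: PrecursorTemplate = DEFAULT_TEMPLATE,
    length_bounds: tuple[int, int] = (6, 12),
) -> LibraryDesign:
    """Parse a design listing like ``"dsk nnk nnk nnu"`` or ``"dsk-(nnk)9-nnu"``.

    Tokens are separated by whitespace or dashes; ``(codon)N`` repeats the
    codon N times.
    """
    tokens = [t for t in re.split(r"[\s\-]+", spec.strip()) if t]
    codons: list[DegenerateCodon] = []
    for tok in tokens:
        m = _REPEAT_RE.match(tok)
        if m:
            codons.extend(
                DegenerateCodon(m.group("codon")) for _ in range(int(m.group("n")))
            )
        else:
            codons.append(DegenerateCodon(tok))
    if not codons:
        raise ValueError(f"empty design spec: {spec!r}")
    return LibraryDesign(tuple(codons), template, length_bounds)
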