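"""Model-guided optimization of degenerate-codon library designs.

A design is scored by combining its mean predicted modification efficiency
``E`` (Monte-Carlo average of classifier/oracle predictions over sampled
peptides) with its theoretical diversity ``D``:

    M = E × (log10 D / log10 D_ref)^γ

where ``D_ref`` is the diversity of the all-``nnk`` design of the same
length.  ``γ`` sets the efficiency/diversity trade-off: the long-insert mode
(γ = 0.5) tolerates diversity losses because long libraries are inherently
diverse, while the short-insert mode (γ = 2.0) penalizes them sharply.  Both
exponents are configurable so alternative functional forms can be swapped in.

The virtual Ala scan fixes one randomized position at a time to the
Ala-encoding ``gcg`` codon and measures the change in ``E``; positions whose
restriction moves ``E`` most are the specificity-determining ones.  Search
routines then rank candidate codons at chosen positions (singly or in
pairs) by ``M``, using common random peptide samples across candidates to
reduce ranking noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .codons import (DegenerateCodon, LibraryDesign, design_aa_profile,
                     design_diversity, parse_design_spec, sample_peptides)

__all__ = [
    "DesignScore",
    "AlaScanResult",
    "MixedLibrary",
    "evaluate_design",
    "score_design",
    "ala_scan",
    "search_position_codons",
    "search_codon_pairs",
    "assemble_mixed_library",
    "reference_mixed_designs",
]

GAMMA_LONG = 0.5
GAMMA_SHORT = 2.0


def _predict(predictor, inserts: Sequence[str]) -> np.ndarray:
    if hasattr(predictor, "predict_fitness"):
        return np.asarray(predictor.predict_fitness(inserts), dtype=float)
    return np.asarray(predictor(inserts), dtype=float)


@dataclass
class DesignScore:
    design: LibraryDesign
    E: float  #: mean predicted modification efficiency, in [0, 1]
    D: int  #: theoretical diversity (distinct stop-free peptides)
    M: float | None = None
    mode: str | None = None  # long | short
    n: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.E <= 1.0:
            raise ValueError("E must be in [0, 1]")
        if self.D < 1:
            raise ValueError("D must be >= 1")


def evaluate_design(
    predictor,
    design: LibraryDesign,
    n: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> DesignScore:
    """Mean predicted modification efficiency and diversity of a design.

    ``E`` is the Monte-Carlo mean of the predictor over ``n`` peptides
    sampled from the design (deterministic given ``seed`` and the predictor
    state).  With ``exhaustive=True`` (only for D ≤ 10^4) the exact
    expectation under the sampling distribution is computed instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    D = design_diversity(design)
    if exhaustive:
        if D > 10_000:
            raise ValueError("exhaustive evaluation limited to designs with D <= 1e4")
        profile = design_aa_profile(design)
        peptides = []
        weights = []
        for combo in product(*[sorted(p) for p in profile.probs]):
            peptides.append("".join(combo))
            weights.append(math.prod(profile.probs[i][a]
                                     for i, a in enumerate(combo)))
        scores = _predict(predictor, peptides)
        E = float(np.dot(scores, np.array(weights)))
        return DesignScore(design, E=min(max(E, 0.0), 1.0), D=D,
                           n=len(peptides), seed=seed)
    peptides = sample_peptides(design, n, seed)
    E = float(_predict(predictor, peptides).mean())
    return DesignScore(design, E=E, D=D, n=n, seed=seed)


def score_design(
    E: float,
    D: int,
    mode: str,
    length: int | None = None,
    d_ref: int | None = None,
    gamma_long: float = GAMMA_LONG,
    gamma_short: float = GAMMA_SHORT,
) -> float:
    """Library score M = E × (log10 D / log10 D_ref)^γ.

    Strictly increasing in both ``E`` and ``D``; the short mode penalizes a
    diversity deficit relative to the all-nnk reference more than the long
    mode (γ_short > γ_long).  ``d_ref`` defaults to 20^length.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    if not 0.0 <= E <= 1.0:
        raise ValueError("E must be in [0, 1]")
    if mode not in ("long", "short"):
        raise ValueError("mode must be 'long' or 'short'")
    if d_ref is None:
        if length is None:
            raise ValueError("need length or d_ref to normalize diversity")
        d_ref = 20 ** length
    gamma = gamma_long if mode == "long" else gamma_short
    if D == 1:
        return 0.0
    return E * (math.log10(D) / math.log10(d_ref)) ** gamma


def _attach_score(ds: DesignScore, mode: str, **score_kw) -> DesignScore:
    ds.M = score_design(ds.E, ds.D, mode, length=len(ds.design), **score_kw)
    ds.mode = mode
    return ds


@dataclass
class AlaScanResult:
    """Per-position effect of fixing each randomized position to Ala (gcg).

    Positions are 1-based, counting from the first insert position.
    ``delta_E[i-1]`` is ``E(position i fixed to Ala) − E(baseline)``.
    """

    baseline: DesignScore
    position_scores: list[DesignScore]
    delta_E: list[float]

    @property
    def positions(self) -> list[int]:
        return list(range(1, len(self.position_scores) + 1))

    def ranked_positions(self) -> list[int]:
        """Positions ordered by |ΔE| descending (ties: lower position)."""
        order = sorted(self.positions,
                       key=lambda i: (-abs(self.delta_E[i - 1]), i))
        return order


def ala_scan(
    predictor,
    base_design: LibraryDesign,
    n: int = 10_000,
    seed: int = 0,
) -> AlaScanResult:
    """Virtual Ala scan of a fully randomized design.

    Requires all insert positions to carry the same codon (a fully random
    baseline); each position in turn is replaced by Ala-encoding ``gcg``
    and the design re-evaluated with the same seed (common random numbers).
    """
    symbols = {c.symbols for c in base_design.insert_codons}
    if len(symbols) != 1:
        raise ValueError(
            "ala_scan expects a fully randomized baseline "
            "(all insert positions carrying the same codon)"
        )
    baseline = evaluate_design(predictor, base_design, n=n, seed=seed)
    scores = []
    deltas = []
    for pos in range(1, len(base_design) + 1):
        variant = base_design.replace_codon(pos, "gcg")
        ds = evaluate_design(predictor, variant, n=n, seed=seed)
        scores.append(ds)
        deltas.append(ds.E - baseline.E)
    return AlaScanResult(baseline, scores, deltas)


def _ranked(scores: list[DesignScore]) -> list[DesignScore]:
    # rank by M desc, tie by E desc, then lexicographic codon listing
    return sorted(scores, key=lambda s: (-s.M, -s.E, s.design.spec))


def search_position_codons(
    predictor,
    base_design: LibraryDesign,
    position: int,
    candidate_codons: Sequence[str | DegenerateCodon],
    mode: str = "long",
    n: int = 10_000,
    seed: int = 0,
    **score_kw,
) -> list[DesignScore]:
    """Rank candidate codon substitutions at one insert position by M.

    All candidates are evaluated with the same base seed (common random
    numbers) so rankings are stable under repetition.
    """
    if not candidate_codons:
        raise ValueError("candidate codon list is empty")
    scores = []
    for cand in candidate_codons:
        variant = base_design.replace_codon(position, cand)
        ds = evaluate_design(predictor, variant, n=n, seed=seed)
        scores.append(_attach_score(ds, mode, **score_kw))
    return _ranked(scores)


def search_codon_pairs(
    predictor,
    base_design: LibraryDesign,
    pos_a: int,
    pos_b: int,
    candidates_a: Sequence[str | DegenerateCodon],
    candidates_b: Sequence[str | DegenerateCodon],
    mode: str = "long",
    n: int = 10_000,
    seed: int = 0,
    **score_kw,
) -> list[DesignScore]:
    """Full cross-product search over codon pairs at two positions."""
    if not candidates_a or not candidates_b:
        raise ValueError("candidate codon lists must be non-empty")
    scores = []
    for ca, cb in product(candidates_a, candidates_b):
        variant = base_design.replace_codon(pos_a, ca).replace_codon(pos_b, cb)
        ds = evaluate_design(predictor, variant, n=n, seed=seed)
        scores.append(_attach_score(ds, mode, **score_kw))
    return _ranked(scores)


@dataclass
class MixedLibrary:
    """Manifest of per-length designs mixed into one selection library."""

    designs: dict[int, LibraryDesign]
    fractions: dict[int, float]
    total_diversity: int

    def to_dict(self) -> dict:
        return {
            "designs": {str(k): d.spec for k, d in sorted(self.designs.items())},
            "fractions": {str(k): self.fractions[k] for k in sorted(self.fractions)},
            "total_diversity": str(self.total_diversity),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def read(cls, path) -> "MixedLibrary":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        designs = {
            int(k): parse_design_spec(v, length_bounds=(1, 64))
            for k, v in raw["designs"].items()
        }
        fractions = {int(k): float(v) for k, v in raw["fractions"].items()}
        lib = assemble_mixed_library(designs, fractions,
                                     required_lengths=sorted(designs))
        assert lib.total_diversity == int(raw["total_diversity"])
        return lib


def assemble_mixed_library(
    designs: Mapping[int, LibraryDesign],
    fractions: Mapping[int, float] | None = None,
    required_lengths: Sequence[int] = tuple(range(6, 13)),
) -> MixedLibrary:
    """Combine per-length designs into a single mixed-library manifest.

    Every required length must be present; mixing is equimolar unless
    explicit fractions are given.  Total diversity is the sum over lengths.
    """
    missing = [length for length in required_lengths if length not in designs]
    if missing:
        raise ValueError(f"missing designs for insert lengths: {missing}")
    for length, d in designs.items():
        if len(d) != length:
            raise ValueError(
                f"design registered for length {length} has {len(d)} codons"
            )
    if fractions is None:
        fractions = {length: 1.0 / len(designs) for length in designs}
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("mixing fractions must sum to 1")
    total = sum(design_diversity(d) for d in designs.values())
    return MixedLibrary(dict(designs), dict(fractions), total)


def reference_mixed_designs(
    template=None, length_bounds=(6, 12)
) -> dict[int, LibraryDesign]:
    """The published-style per-length map: ``dsk-(nnk)_9-nnu`` at length 11,
    ``dsk-(nnk)_10-nnu`` at 12, and ``dbk-(nnk)_(n-1)`` for lengths 6–10."""
    kw = {"length_bounds": length_bounds}
    if template is not None:
        kw["template"] = template
    out = {}
    for n in range(6, 11):
        out[n] = parse_design_spec(f"dbk (nnk){n - 1}", **kw)
    out[11] = parse_design_spec("dsk (nnk)9 nnu", **kw)
    out[12] = parse_design_spec("dsk (nnk)10 nnu", **kw)
    return out
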