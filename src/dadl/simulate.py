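"""Synthetic selection/antiselection campaign simulator.

Simulates mRNA-display campaigns over a degenerate-codon library under the
rule oracle: DNA variants are drawn codon-by-codon from the design (amber
stops allowed at the DNA level — such variants are damaged and never
mature), each copy matures with probability ``time_factor × oracle(insert)``,
selection keeps matured copies and antiselection keeps unmatured ones,
survivors are amplified by multinomial resampling with per-base PCR
mutation, and every round can be emitted as Phred+33 FASTQ.

Default scales are desk-scale (10^4–10^5 variants), standing in for the
experimental 6 × 10^12 molecules; all stochastic steps are seeded.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .codons import (AA_ALPHABET, DEFAULT_TEMPLATE, LibraryDesign,
                     PrecursorTemplate, expand_codon)
from .oracle import RuleOracle

__all__ = [
    "Pool",
    "RoundParams",
    "RoundSummary",
    "SimulationError",
    "generate_pool",
    "simulate_round",
    "emit_fastq",
    "run_campaign",
    "CampaignResult",
]

#: one concrete codon per residue, used for the fixed template regions
_AA_CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(RuntimeError):
    pass


def displayed_library_size(n_mrna: float, display_rate: float = 0.04) -> float:
    """Expected count of displayed thiopeptide compounds.

    Of the mRNA molecules entering in-vitro translation and enzymatic
    treatment, only a fraction ends up displaying a fully matured
    thiopeptide (~4% for these precursor libraries); the product
    ``n_mrna × display_rate`` estimates the true compound library size.
    """
    if not 0.0 <= display_rate <= 1.0:
        raise ValueError("display_rate must be in [0, 1]")
    return n_mrna * display_rate


def _aa_to_dna(seq: str) -> str:
    return "".join(_AA_CODON[a] for a in seq)


@dataclass
class Pool:
    """A population of DNA variants with copy counts.

    ``variants`` maps the DNA of the read region
    (``core_pre + insert + core_post + linker``) to its copy count.
    """

    variants: dict[str, int]
    design: LibraryDesign
    round_index: int = 0
    mode: str = "initial"  # selection | antiselection | initial

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.variants.values()):
            raise ValueError("copy counts must be >= 1")

    @property
    def total_copies(self) -> int:
        return sum(self.variants.values())

    @property
    def unique_count(self) -> int:
        return len(self.variants)

    def inserts(self) -> dict[str, str | None]:
        """Translate each variant; ``None`` marks damaged variants
        (stop codon in the insert or a corrupted fixed region).
        Cached: variants are fixed after construction."""
        if not hasattr(self, "_inserts_cache"):
            self._inserts_cache = {
                dna: _variant_insert(dna, self.design) for dna in self.variants
            }
        return self._inserts_cache

    def insert_multiset(self) -> Counter:
        """Copy-weighted multiset of valid (undamaged) inserts."""
        out: Counter = Counter()
        for dna, insert in self.inserts().items():
            if insert is not None:
                out[insert] += self.variants[dna]
        return out


def _variant_insert(dna: str, design: LibraryDesign) -> str | None:
    """Light-weight in-frame parse used by the simulator's bookkeeping."""
    tpl = design.template
    prot = str(Seq(dna[: 3 * (len(dna) // 3)]).translate())
    pre, post = tpl.core_pre, tpl.core_post
    lo, hi = design.length_bounds
    best = None
    if not prot.startswith(pre):
        candidate = None
    else:
        for length in range(lo, hi + 1):
            a = len(pre) + length
            b = a + len(post)
            if b > len(prot):
                break
            if prot[a:b] == post:
                best = prot[len(pre):a]
                break
        candidate = best
    if candidate is None or "*" in candidate:
        return None
    if any(res not in AA_ALPHABET for res in candidate):
        return None
    return candidate


@dataclass(frozen=True)
class RoundParams:
    """Knobs of one simulated round.

    time_factor scales the per-copy maturation probability (1.0 = the full
    8 h enzymatic incubation; 0.5 models the shortened 4 h reaction).
    mutation_rate is the per-base per-round PCR error rate.
    amplification_target is the post-amplification copy total (None keeps
    the pre-round total).  reads_per_round caps sequencing depth when
    emitting FASTQ (None = one read per copy).
    """

    time_factor: float = 1.0
    mutation_rate: float = 1e-4
    amplification_target: int | None = None
    reads_per_round: int | None = None
    quality_mean: float = 37.0
    quality_sd: float = 3.0
    quality_min: int = 2
    quality_max: int = 41
    sequencing_errors: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.time_factor <= 1.0:
            raise ValueError("time_factor must be in [0, 1]")
        if not 0.0 <= self.mutation_rate < 0.1:
            raise ValueError("mutation_rate must be small (<0.1 per base)")


@dataclass
class RoundSummary:
    round_index: int
    mode: str
    recovery_fraction: float
    mean_oracle_fitness: float
    unique_variants: int
    total_copies: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise ValueError("recovery fraction must be in [0, 1]")


def generate_pool(
    design: LibraryDesign,
    n_variants: int,
    seed: int | np.random.Generator = 0,
) -> Pool:
    """Draw an initial pool of DNA variants from the design.

    Concrete codons are drawn uniformly from each position's expansion;
    amber stops therefore occur at their natural DNA-level rate and the
    resulting variants are damaged (they never mature and are rejected by
    the preprocessor downstream).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tpl = design.template
    pre_dna = _aa_to_dna(tpl.core_pre)
    post_dna = _aa_to_dna(tpl.core_post + tpl.linker)
    expansions = [expand_codon(c) for c in design.insert_codons]
    cols = [
        np.array(exp)[rng.integers(0, len(exp), size=n_variants)]
        for exp in expansions
    ]
    variants: Counter = Counter()
    for row in zip(*cols):
        variants[pre_dna + "".join(row) + post_dna] += 1
    return Pool(dict(variants), design, round_index=0, mode="initial")


def _mutate(variants: dict[str, int], rate: float,
            rng: np.random.Generator) -> dict[str, int]:
    """Apply per-base point mutations: each copy-base flips with prob rate."""
    if rate <= 0:
        return dict(variants)
    out: Counter = Counter()
    for dna, count in variants.items():
        length = len(dna)
        n_mut = rng.binomial(count * length, rate)
        n_mut = min(n_mut, count)  # at most one mutation per copy at these rates
        out[dna] += count - n_mut
        for _ in range(n_mut):
            pos = int(rng.integers(length))
            old = dna[pos]
            new = old
            while new == old:
                new = chr(_BASES[rng.integers(4)])
            out[dna[:pos] + new + dna[pos + 1:]] += 1
    if 0 in out.values():
        out = Counter({k: v for k, v in out.items() if v > 0})
    return dict(out)


def simulate_round(
    pool: Pool,
    oracle: RuleOracle,
    mode: str,
    params: RoundParams = RoundParams(),
    seed: int | np.random.Generator = 0,
) -> tuple[Pool, RoundSummary]:
    """One selection or antiselection round.

    Each copy matures with probability ``time_factor × oracle(insert)``
    (damaged variants never mature).  Selection keeps matured copies,
    antiselection keeps unmatured ones; kept + discarded equals the input
    copy count exactly.  Survivors are resampled with replacement to the
    amplification target with per-base PCR mutation.
    """
    if mode not in ("selection", "antiselection"):
        raise ValueError("mode must be 'selection' or 'antiselection'")
    if not pool.variants:
        raise SimulationError("empty pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dnas = list(pool.variants)
    counts = np.array([pool.variants[d] for d in dnas])
    inserts = pool.inserts()
    valid = [inserts[d] for d in dnas]
    fitness = np.zeros(len(dnas))
    idx_valid = [i for i, s in enumerate(valid) if s is not None]
    if idx_valid:
        fitness[idx_valid] = oracle.predict_fitness([valid[i] for i in idx_valid])
    p_mature = params.time_factor * fitness

    matured = rng.binomial(counts, p_mature)
    unmatured = counts - matured
    assert int((matured + unmatured).sum()) == pool.total_copies
    recovery = float(matured.sum() / counts.sum())

    kept = matured if mode == "selection" else unmatured
    kept_total = int(kept.sum())
    if kept_total == 0:
        raise SimulationError(
            f"no copies survived the {mode} partition; "
            "use a larger pool or a weaker bottleneck"
        )

    target = params.amplification_target or pool.total_copies
    amplified = rng.multinomial(target, kept / kept_total)
    survivors = {d: int(c) for d, c in zip(dnas, amplified) if c > 0}
    survivors = _mutate(survivors, params.mutation_rate, rng)

    new_pool = Pool(survivors, pool.design,
                    round_index=pool.round_index + 1, mode=mode)
    mean_fit = _pool_mean_fitness(new_pool, oracle)
    summary = RoundSummary(
        round_index=new_pool.round_index,
        mode=mode,
        recovery_fraction=recovery,
        mean_oracle_fitness=mean_fit,
        unique_variants=new_pool.unique_count,
        total_copies=new_pool.total_copies,
    )
    return new_pool, summary


def _pool_mean_fitness(pool: Pool, oracle: RuleOracle) -> float:
    """Copy-weighted mean oracle fitness; damaged variants count as 0."""
    inserts = pool.inserts()
    dnas = list(pool.variants)
    weights = np.array([pool.variants[d] for d in dnas], dtype=float)
    fit = np.zeros(len(dnas))
    idx = [i for i, d in enumerate(dnas) if inserts[d] is not None]
    if idx:
        fit[idx] = oracle.predict_fitness([inserts[dnas[i]] for i in idx])
    return float((fit * weights).sum() / weights.sum())


def emit_fastq(
    pool: Pool,
    params: RoundParams,
    path,
    seed: int | np.random.Generator = 0,
) -> int:
    """Write the pool as Phred+33 FASTQ; returns the number of reads.

    One read per copy unless ``params.reads_per_round`` caps the depth, in
    which case reads are a multinomial subsample of the pool.  Per-base
    qualities are drawn from a clipped normal distribution; when
    ``params.sequencing_errors`` is set each base is miscalled with the
    probability its own quality implies (10^(-q/10)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dnas = list(pool.variants)
    counts = np.array([pool.variants[d] for d in dnas])
    if params.reads_per_round is not None and params.reads_per_round < counts.sum():
        counts = rng.multinomial(params.reads_per_round, counts / counts.sum())
    n_reads = 0
    with open(path, "w") as fh:
        for dna, n in zip(dnas, counts):
            n = int(n)
            if n == 0:
                continue
            length = len(dna)
            q = np.clip(
                np.rint(rng.normal(params.quality_mean, params.quality_sd,
                                   size=(n, length))),
                params.quality_min, params.quality_max,
            ).astype(np.uint8)
            seqs = np.tile(np.frombuffer(dna.encode(), dtype=np.uint8),
                           (n, 1))
            if params.sequencing_errors:
                p_err = 10.0 ** (-q.astype(float) / 10.0)
                err_rows, err_cols = np.nonzero(rng.random((n, length)) < p_err)
                for r, c in zip(err_rows, err_cols):
                    choices = _BASES[_BASES != seqs[r, c]]
                    seqs[r, c] = choices[rng.integers(3)]
            quals = (q + 33).tobytes().decode("latin-1")
            for i in range(n):
                n_reads += 1
                fh.write(
                    f"@r{pool.round_index}_{pool.mode}_{n_reads}\n"
                    f"{seqs[i].tobytes().decode()}\n+\n"
                    f"{quals[i * length:(i + 1) * length]}\n"
                )
    return n_reads


@dataclass
class CampaignResult:
    summaries: pd.DataFrame
    fastq_paths: dict[tuple[str, int], Path]
    initial_pool: Pool
    final_pools: dict[str, Pool]
    manifest_path: Path | None = None


def run_campaign(
    design: LibraryDesign,
    oracle: RuleOracle,
    outdir,
    n_rounds: int = 6,
    n_variants: int = 20_000,
    params: RoundParams = RoundParams(),
    seed: int = 0,
    time_factors: Sequence[float] | None = None,
) -> CampaignResult:
    """Run paired selection and antiselection campaigns from a shared pool.

    Writes one FASTQ per round per campaign plus a summary table and a JSON
    manifest into ``outdir``.  ``time_factors`` optionally overrides the
    per-round reaction-time factor (e.g. halved in late rounds).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    initial = generate_pool(design, n_variants, rng)

    summaries = []
    fastq_paths: dict[tuple[str, int], Path] = {}
    final_pools: dict[str, Pool] = {}
    for mode in ("selection", "antiselection"):
        pool = Pool(dict(initial.variants), design, 0, mode)
        for r in range(n_rounds):
            tf = (time_factors[r] if time_factors is not None
                  else params.time_factor)
            round_params = RoundParams(**{**asdict(params), "time_factor": tf})
            pool, summary = simulate_round(pool, oracle, mode, round_params, rng)
            path = outdir / f"{mode}_round{pool.round_index}.fastq"
            emit_fastq(pool, round_params, path, rng)
            fastq_paths[(mode, pool.round_index)] = path
            summaries.append(asdict(summary))
        final_pools[mode] = pool

    table = pd.DataFrame(summaries)
    table_path = outdir / "round_summaries.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    manifest = {
        "design": design.spec,
        "n_rounds": n_rounds,
        "n_variants": n_variants,
        "seed": seed,
        "params": asdict(params),
        "fastq": {f"{m}_round{r}": p.name for (m, r), p in fastq_paths.items()},
        "summary_table": table_path.name,
    }
    manifest_path = outdir / "campaign_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return CampaignResult(table, fastq_paths, initial, final_pools, manifest_path)
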