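"""Reduced-genetic-code ("family box") codon statistics.

A family box is a four-codon box of the standard genetic code whose amino
acid is fixed by the first two bases alone — third-position-independent
coding, hypothesised to be the oldest layer of the code.  Exactly 8 of the
16 boxes qualify (Ala, Arg CGN, Gly, Leu CUN, Pro, Ser UCN, Thr, Val),
i.e. 32 of the 64 codons.  For each pool sequence the longest run of
consecutive family-box codons (frame 0 from the 5' end) bounds the length
of any peptide encodable with a family-box-only primordial code; observed
pools are compared against a matched-length null of sequences with
uniform, unbiased codon composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .seqtools import validate_rna
from .pools import PoolRecord, SequencePool

__all__ = [
    "CodonStretchResult",
    "EnrichmentSummary",
    "family_box_set",
    "longest_family_stretch",
    "family_fraction",
    "codon_stats",
    "null_pool",
    "simulate_null",
    "stretch_enrichment",
]

_BASES = "UCAG"
_ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class CodonStretchResult:
    """Per-sequence family-box codon statistics."""

    id: str
    n_codons: int
    longest_family_stretch: int
    family_fraction: float


@lru_cache(maxsize=1)
def family_box_set() -> frozenset[str]:
    """The 32 family-box codons, derived from the standard code.

    A box (fixed first two bases) is a family box when its four codons all
    translate to the same amino acid; a stop codon anywhere in the box
    breaks third-position invariance, so boxes containing stops are
    excluded.
    """
    table = CodonTable.unambiguous_rna_by_id[1]
    stops = set(table.stop_codons)
    boxes: list[str] = []
    for first in _BASES:
        for second in _BASES:
            codons = [first + second + third for third in _BASES]
            if any(c in stops for c in codons):
                continue
            if len({table.forward_table[c] for c in codons}) == 1:
                boxes.extend(codons)
    return frozenset(boxes)


def _codons(seq: str) -> list[str]:
    """Frame-0 codons from the 5' end; trailing 1-2 nt are dropped."""
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def longest_family_stretch(seq: str) -> int:
    """Longest run of consecutive family-box codons (frame 0)."""
    if seq:
        validate_rna(seq)
    fam = family_box_set()
    best = run = 0
    for codon in _codons(seq):
        run = run + 1 if codon in fam else 0
        best = max(best, run)
    return best


def family_fraction(pool: SequencePool) -> float:
    """Weighted fraction of the pool's complete codons that are family-box.

    Returns NaN when the pool contributes no complete codon.
    """
    if len(pool) == 0:
        raise ValueError("pool is empty")
    fam = family_box_set()
    num = den = 0.0
    for rec in pool:
        codons = _codons(rec.sequence)
        den += rec.weight * len(codons)
        num += rec.weight * sum(1 for c in codons if c in fam)
    return num / den if den > 0 else float("nan")


def codon_stats(pool: SequencePool) -> pd.DataFrame:
    """Per-sequence table: id, n_codons, longest_family_stretch, family_fraction."""
    fam = family_box_set()
    rows = []
    for rec in pool:
        codons = _codons(rec.sequence)
        n_fam = sum(1 for c in codons if c in fam)
        rows.append(
            (
                rec.id,
                len(codons),
                longest_family_stretch(rec.sequence),
                n_fam / len(codons) if codons else float("nan"),
            )
        )
    return pd.DataFrame(
        rows, columns=["id", "n_codons", "longest_family_stretch", "family_fraction"]
    )


def null_pool(lengths, n_reps: int, seed: int | None) -> SequencePool:
    """Matched-length null pool with unbiased codon composition.

    For each replicate and each input length, one sequence of that length
    is built from codons drawn i.i.d. uniformly over all 64 (trailing 1-2
    nt, if the length is not a multiple of 3, are uniform bases).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lengths = [int(x) for x in lengths]
    if any(x < 0 for x in lengths):
        raise ValueError("lengths must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_reps):
        for i, length in enumerate(lengths):
            n_cod, rem = divmod(length, 3)
            parts = [_ALL_CODONS[j] for j in rng.integers(0, 64, size=n_cod)]
            if rem:
                parts.append("".join("ACGU"[j] for j in rng.integers(0, 4, size=rem)))
            seq = "".join(parts)
            if seq:
                records.append(PoolRecord(id=f"null_r{rep}_{i}", sequence=seq))
    return SequencePool(records)


def simulate_null(lengths, n_reps: int, seed: int | None) -> np.ndarray:
    """Null distribution of the longest family-box stretch.

    Returns the stretch value of every null sequence (n_reps replicates of
    the matched length list), as a flat integer array.
    """
    pool = null_pool(lengths, n_reps, seed)
    return np.array([longest_family_stretch(rec.sequence) for rec in pool], dtype=int)


@dataclass(frozen=True)
class EnrichmentSummary:
    """Observed-vs-null comparison of family-box stretch lengths."""

    observed_freq: pd.Series
    null_freq: pd.Series
    mean_observed: float
    mean_null: float
    mean_difference: float
    exceedance_p: float


def stretch_enrichment(
    observed, null: np.ndarray, n_resample: int = 2000, seed: int | None = 0
) -> EnrichmentSummary:
    """Compare observed stretch lengths against a simulated null.

    ``observed`` is a list of CodonStretchResult or of integers.  The
    summary holds per-length frequency tables (each summing to 1), the
    mean difference, and an empirical exceedance probability: the fraction
    of size-matched null resamples whose mean reaches the observed mean.
    No parametric test is used.
    """
    obs = np.array(
        [
            getattr(x, "longest_family_stretch", x)
            for x in observed
        ],
        dtype=float,
    )
    null = np.asarray(null, dtype=float)
    if obs.size == 0 or null.size == 0:
        raise ValueError("observed and null must be nonempty")
    support = np.arange(0, int(max(obs.max(), null.max())) + 1)
    obs_freq = pd.Series(
        [(obs == v).mean() for v in support], index=support, name="observed"
    )
    null_freq = pd.Series(
        [(null == v).mean() for v in support], index=support, name="null"
    )
    rng = np.random.default_rng(seed)
    resample_means = rng.choice(null, size=(n_resample, obs.size), replace=True).mean(
        axis=1
    )
    exceed = float((resample_means >= obs.mean()).mean())
    return EnrichmentSummary(
        observed_freq=obs_freq,
        null_freq=null_freq,
        mean_observed=float(obs.mean()),
        mean_null=float(null.mean()),
        mean_difference=float(obs.mean() - null.mean()),
        exceedance_p=exceed,
    )
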