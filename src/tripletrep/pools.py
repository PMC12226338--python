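"""Classification and composition analysis of emergent RNA sequence pools.

Sequencing of open-ended triplet replication reactions yields pools of
short RNAs.  Many are fragments of the polymerase ribozyme's own (+) or
(-) strands — the ribozyme serves as an adventitious template — while
others are de novo sequences with no ribozyme homology.  This module
classifies pool records by exact longest-common-substring matching against
a reference of ribozyme (+) strands (the (-) strands are their reverse
complements), maps homologous footprints positionally, and tracks
composition drift (GC content, Chargaff G/C and A/U balance) across
replication cycles.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqtools import reverse_complement, validate_rna

__all__ = [
    "PoolRecord",
    "SequencePool",
    "RibozymeReference",
    "ClassifiedSequence",
    "CompositionStats",
    "CLASS_LABELS",
    "longest_match",
    "classify",
    "classify_pool",
    "map_sites",
    "class_proportions",
    "composition_stats",
    "uniqueness_fraction",
    "register_class",
]

#: Classification labels, in reporting order.
CLASS_LABELS = ("minus_homologous", "plus_homologous", "ambiguous", "no_homology")


@dataclass
class PoolRecord:
    """One weighted pool sequence.

    ``weight`` is a per-record abundance weight (read count or fraction);
    ``lane_intensity`` is the densitometry scale of the gel lane the
    record came from; ``label`` optionally carries a truth or assigned
    class.
    """

    id: str
    sequence: str
    weight: float = 1.0
    cycle: int = 0
    lane_intensity: float = 1.0
    label: str | None = None

    def __post_init__(self) -> None:
        validate_rna(self.sequence, name=f"record {self.id!r}")
        if not math.isfinite(self.weight) or self.weight < 0:
            raise ValueError(f"record {self.id!r}: weight must be finite and >= 0")
        if self.lane_intensity < 0:
            raise ValueError(f"record {self.id!r}: lane_intensity must be >= 0")
        if self.cycle < 0:
            raise ValueError(f"record {self.id!r}: cycle must be >= 0")


@dataclass
class SequencePool:
    """A weighted collection of RNA records (one sequencing/gel snapshot)."""

    records: list[PoolRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "class_truth": [r.label for r in self.records],
                "cycle": [r.cycle for r in self.records],
                "weight": [r.weight for r in self.records],
                "lane_intensity": [r.lane_intensity for r in self.records],
            }
        )


@dataclass(frozen=True)
class RibozymeReference:
    """Named (+)-strand sequences of the ribozyme subunits.

    (-) strands are always derived as reverse complements, never stored.
    """

    subunits: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError("reference needs at least one subunit")
        for name, seq in self.subunits.items():
            validate_rna(seq, name=f"subunit {name!r}")

    def minus(self, name: str) -> str:
        """Reverse complement ((-) strand) of a subunit."""
        return reverse_complement(self.subunits[name])


@dataclass
class ClassifiedSequence:
    """Classification of one pool record against the reference.

    ``match_intervals`` holds every (subunit, strand, start, end) interval
    achieving ``best_match_len``; (-)-strand intervals are reported as the
    footprint on the (+)-strand coordinate axis (0-based, half-open) so
    both strands of a subunit share one axis.  ``assigned_site`` is the
    single interval chosen for positional mapping, when one was drawn.
    """

    id: str
    label: str
    best_match_len: int
    match_intervals: list[tuple[str, str, int, int]]
    assigned_site: tuple[str, str, int, int] | None = None


def longest_match(seq: str, ref: str) -> tuple[int, list[tuple[int, int]]]:
    """Longest common substring of two RNA strings.

    Returns the match length and every (query_offset, ref_offset) pair at
    which a maximal-length match starts.  Row-vectorised dynamic
    programming over common-suffix lengths; O(len(seq) * len(ref)).
    """
    validate_rna(seq, name="query")
    validate_rna(ref, name="reference")
    q = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    r = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    prev = np.zeros(r.size + 1, dtype=np.int64)
    cur = np.zeros(r.size + 1, dtype=np.int64)
    best = 0
    positions: list[tuple[int, int]] = []
    for i in range(q.size):
        cur[:] = 0
        eq = r == q[i]
        cur[1:][eq] = prev[:-1][eq] + 1
        row_max = int(cur.max())
        if row_max > best:
            best = row_max
            positions = [
                (i - best + 1, int(j) - best + 1)
                for j in np.nonzero(cur[1:] == best)[0]
            ]
        elif best > 0 and row_max == best:
            positions.extend(
                (i - best + 1, int(j) - best + 1)
                for j in np.nonzero(cur[1:] == best)[0]
            )
        prev, cur = cur, prev
    return best, positions


def classify(
    seq: str,
    ref: RibozymeReference,
    min_match: int = 12,
    rng: np.random.Generator | None = None,
    record_id: str = "",
) -> ClassifiedSequence:
    """Classify one sequence by homology to the reference strands.

    A match of at least ``min_match`` contiguous nucleotides to a (+)
    strand makes the record plus_homologous; to a (-) strand (i.e. the
    record is complementary to the (+) strand) minus_homologous; to both,
    ambiguous; to neither, no_homology.  ``match_intervals`` retains all
    ties at the best match length.  If ``rng`` is given and the record is
    homologous, one interval is drawn uniformly as ``assigned_site``.
    """
    if min_match < 6:
        raise ValueError("min_match must be >= 6")
    hits: list[tuple[int, str, str, int, int]] = []
    best_by_strand = {"+": 0, "-": 0}
    for name, plus in ref.subunits.items():
        n = len(plus)
        length, pos = longest_match(seq, plus)
        if length > 0:
            best_by_strand["+"] = max(best_by_strand["+"], length)
            hits.extend((length, name, "+", ro, ro + length) for _, ro in pos)
        length, pos = longest_match(seq, reverse_complement(plus))
        if length > 0:
            best_by_strand["-"] = max(best_by_strand["-"], length)
            # footprint of a (-)-strand match on the (+)-strand axis
            hits.extend(
                (length, name, "-", n - ro - length, n - ro) for _, ro in pos
            )
    plus_hit = best_by_strand["+"] >= min_match
    minus_hit = best_by_strand["-"] >= min_match
    if plus_hit and minus_hit:
        label = "ambiguous"
    elif plus_hit:
        label = "plus_homologous"
    elif minus_hit:
        label = "minus_homologous"
    else:
        label = "no_homology"
    best = max(best_by_strand.values())
    intervals = sorted(
        {(name, strand, s, e) for length, name, strand, s, e in hits if length == best}
    )
    assigned = None
    if rng is not None and label != "no_homology" and intervals:
        assigned = intervals[int(rng.integers(len(intervals)))]
    return ClassifiedSequence(
        id=record_id,
        label=label,
        best_match_len=best,
        match_intervals=intervals,
        assigned_site=assigned,
    )


def classify_pool(
    pool: SequencePool,
    ref: RibozymeReference,
    min_match: int = 12,
    seed: int | None = None,
) -> list[ClassifiedSequence]:
    """Classify every record of a pool; a seed enables site assignment."""
    rng = np.random.default_rng(seed) if seed is not None else None
    return [
        classify(rec.sequence, ref, min_match=min_match, rng=rng, record_id=rec.id)
        for rec in pool
    ]


def map_sites(
    pool: SequencePool,
    ref: RibozymeReference,
    min_match: int = 12,
    seed: int = 0,
) -> dict[tuple[str, str], np.ndarray]:
    """Positional footprint histograms per (subunit, strand).

    Each homologous record contributes weight x lane_intensity to every
    position of exactly one of its best-length match intervals, chosen
    uniformly at random (multi-mappers are randomly assigned to one site).
    Histogram axes are (+)-strand coordinates; total deposited mass equals
    the sum of weight x lane_intensity x interval_length over assignments.
    """
    hist = {
        (name, strand): np.zeros(len(plus))
        for name, plus in ref.subunits.items()
        for strand in "+-"
    }
    rng = np.random.default_rng(seed)
    for rec in pool:
        cls = classify(rec.sequence, ref, min_match=min_match, rng=rng,
                       record_id=rec.id)
        if cls.assigned_site is None:
            continue
        name, strand, start, end = cls.assigned_site
        hist[(name, strand)][start:end] += rec.weight * rec.lane_intensity
    return hist


def class_proportions(
    pools: SequencePool | Sequence[SequencePool],
    ref: RibozymeReference,
    min_match: int = 12,
    length_band: tuple[int, int] = (9, 27),
) -> pd.DataFrame:
    """Weight-normalised class fractions per replication cycle.

    Restricted to records whose length falls inside ``length_band``
    (inclusive; default the 9-27 nt band).  Returns a DataFrame indexed by
    cycle with one column per class label; rows sum to 1.  An empty length
    band yields an empty frame.
    """
    if isinstance(pools, SequencePool):
        pools = [pools]
    if not pools:
        raise ValueError("need at least one pool")
    lo, hi = length_band
    mass: dict[int, Counter] = {}
    for pool in pools:
        for rec in pool:
            if not lo <= len(rec.sequence) <= hi:
                continue
            cls = classify(rec.sequence, ref, min_match=min_match,
                           record_id=rec.id)
            mass.setdefault(rec.cycle, Counter())[cls.label] += rec.weight
    if not mass:
        return pd.DataFrame(columns=list(CLASS_LABELS)).rename_axis("cycle")
    rows = {}
    for cycle in sorted(mass):
        total = sum(mass[cycle].values())
        rows[cycle] = {
            label: (mass[cycle].get(label, 0.0) / total if total > 0 else 0.0)
            for label in CLASS_LABELS
        }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(CLASS_LABELS))
    return out.rename_axis("cycle")


@dataclass(frozen=True)
class CompositionStats:
    """Weighted base composition; undefined ratios are NaN, never errors."""

    gc_fraction: float
    g_to_c_ratio: float
    a_to_u_ratio: float


def composition_stats(
    pool: SequencePool, labels: Iterable[str] | None = None
) -> CompositionStats:
    """Weighted nucleotide composition of a pool.

    ``labels`` optionally restricts to records whose ``label`` is in the
    given set (e.g. only sequences classed as having no ribozyme
    homology).  Counts are weighted by record weight.  A zero denominator
    (no C, or no U) yields NaN for the affected ratio.
    """
    wanted = set(labels) if labels is not None else None
    counts = {b: 0.0 for b in "ACGU"}
    for rec in pool:
        if wanted is not None and rec.label not in wanted:
            continue
        for base in "ACGU":
            counts[base] += rec.weight * rec.sequence.count(base)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("pool is empty after filtering")
    gc = (counts["G"] + counts["C"]) / total
    g_to_c = counts["G"] / counts["C"] if counts["C"] > 0 else float("nan")
    a_to_u = counts["A"] / counts["U"] if counts["U"] > 0 else float("nan")
    return CompositionStats(gc_fraction=gc, g_to_c_ratio=g_to_c, a_to_u_ratio=a_to_u)


def uniqueness_fraction(pool: SequencePool) -> float:
    """Fraction of records whose sequence occurs exactly once (unweighted)."""
    if len(pool) == 0:
        raise ValueError("pool is empty")
    counts = Counter(rec.sequence for rec in pool)
    singletons = sum(1 for c in counts.values() if c == 1)
    return singletons / len(pool)


def register_class(length: int, offsets: Iterable[int]) -> str | None:
    """Length-register label for a product length.

    Products advance in 3-nt steps from a fixed offset (0 for pure triplet
    chains, 5 when a terminal pentamer substrate was incorporated), so a
    length belongs to register offset o when length = 3n + o.  Offsets
    congruent mod 3 are indistinguishable and raise; a length shorter than
    its only congruent offset, or congruent to none, returns None.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    offsets = sorted(set(offsets))
    residues = [o % 3 for o in offsets]
    if len(set(residues)) != len(residues):
        raise ValueError("ambiguous offsets: two offsets are congruent mod 3")
    for o, res in zip(offsets, residues):
        if length % 3 == res and length >= o:
            return "(3)n" if o == 0 else f"(3)n+{o}"
    return None
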