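"""Seeded synthetic data with the statistical structure of the real assays.

Three generators stand in for the study's raw data so every analysis stage
is testable without downloads:

* emergent sequence pools — a mixture of fragments complementary to a
  ribozyme reference ((-)-strand homologous), fragments of the reference
  itself ((+)-strand homologous), de novo GC-rich sequences that respect
  Chargaff's rule at the pool level, and uniform-random junk (the
  classifier's null);
* delay series — free-strand fractions after a reannealing delay,
  following the second-order closed form plus additive Gaussian noise;
* amplification trajectories — per-cycle copy numbers following
  exponential growth to a plateau with multiplicative lognormal noise.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cycling import CycleProtocol
from .kinetics import AnnealingParams, fraction_free
from .pools import PoolRecord, RibozymeReference, SequencePool
from .seqtools import reverse_complement

__all__ = [
    "PoolGenSpec",
    "ToyReference",
    "gen_reference",
    "gen_emergent_pool",
    "gen_delay_series",
    "gen_amp_trajectory",
]

# The reference type is shared with the analysis side: named (+) strands,
# (-) strands derived as reverse complements.
ToyReference = RibozymeReference

#: Generator class names, in weight order.
POOL_CLASSES = ("minus_homologous", "plus_homologous", "de_novo", "junk")


@dataclass(frozen=True)
class PoolGenSpec:
    """Parameters of one synthetic pool snapshot.

    ``class_weights`` are the mixture proportions over
    (minus_homologous, plus_homologous, de_novo, junk) and must sum to 1.
    ``length_range_nt`` bounds generated lengths (inclusive); both ends
    must be multiples of 3 in [9, 60] — products are synthesised in
    triplet register.  ``gc_target`` sets the de novo GC richness.
    ``lane_intensity`` is carried onto every record (densitometry units).
    """

    seed: int
    n_sequences: int
    cycle_index: int = 0
    class_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    length_range_nt: tuple[int, int] = (9, 60)
    gc_target: float = 0.6
    lane_intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.cycle_index < 0:
            raise ValueError("cycle_index must be >= 0")
        if len(self.class_weights) != 4 or any(w < 0 for w in self.class_weights):
            raise ValueError("class_weights must be 4 non-negative proportions")
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("class_weights must sum to 1")
        lo, hi = self.length_range_nt
        if lo % 3 or hi % 3 or not (9 <= lo <= hi <= 60):
            raise ValueError(
                "length_range_nt must be multiples of 3 within [9, 60]"
            )
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must lie in [0, 1]")
        if self.lane_intensity < 0:
            raise ValueError("lane_intensity must be >= 0")


def _biased_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=n, p=p)])


def gen_reference(seed: int, lengths, gc: float) -> RibozymeReference:
    """Random toy reference with exact lengths and near-exact GC content.

    Each strand carries round(gc * L) G/C bases (split as evenly as
    possible between G and C, likewise A/U), placed by a seeded shuffle,
    so the realised GC fraction deviates from ``gc`` by at most 1/(2L).
    Subunits are named S1, S2, ...
    """
    lengths = [int(x) for x in lengths]
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    if any(x < 30 for x in lengths):
        raise ValueError("reference strands must be >= 30 nt")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    subunits: dict[str, str] = {}
    for i, length in enumerate(lengths, start=1):
        n_gc = round(gc * length)
        n_au = length - n_gc
        bases = (
            "G" * (n_gc // 2 + n_gc % 2)
            + "C" * (n_gc // 2)
            + "A" * (n_au // 2 + n_au % 2)
            + "U" * (n_au // 2)
        )
        arr = np.array(list(bases))
        rng.shuffle(arr)
        subunits[f"S{i}"] = "".join(arr)
    return RibozymeReference(subunits=subunits)


def _random_triplet(rng: np.random.Generator, gc: float) -> str:
    return _biased_bases(rng, 3, gc)


def _de_novo_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    # complementary triplet pairs enforce Chargaff balance in expectation at
    # the pool level without forcing per-sequence complementarity
    n_trip = length // 3
    triplets: list[str] = []
    for _ in range(n_trip // 2):
        t = _random_triplet(rng, gc)
        triplets.extend((t, reverse_complement(t)))
    if n_trip % 2:
        triplets.append(_random_triplet(rng, gc))
    rng.shuffle(triplets)
    return "".join(triplets)


def gen_emergent_pool(ref: RibozymeReference, spec: PoolGenSpec) -> SequencePool:
    """Synthetic pool snapshot mixing the four sequence classes.

    minus_homologous records are reverse complements of contiguous
    substrings of a (+) strand; plus_homologous records are contiguous
    substrings; fragment endpoints are snapped to triplet boundaries of
    the reference 5' end.  de_novo records are built from complementary
    triplet pairs (Chargaff-balanced in expectation, GC-rich per
    ``gc_target``); junk records are uniform i.i.d. nucleotides.  Records
    carry the spec's cycle index and lane intensity and a truth label.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range_nt
    max_len = hi
    names = list(ref.subunits)
    for name in names:
        if len(ref.subunits[name]) <= max_len:
            raise ValueError(
                f"subunit {name!r} ({len(ref.subunits[name])} nt) must be longer "
                f"than the maximum fragment length ({max_len} nt)"
            )
    counts = rng.multinomial(spec.n_sequences, spec.class_weights)
    lengths_choices = np.arange(lo, hi + 1, 3)
    records: list[PoolRecord] = []
    idx = 0
    for cls, n_cls in zip(POOL_CLASSES, counts):
        for _ in range(int(n_cls)):
            length = int(rng.choice(lengths_choices))
            if cls in ("minus_homologous", "plus_homologous"):
                name = names[int(rng.integers(len(names)))]
                plus = ref.subunits[name]
                start = 3 * int(rng.integers((len(plus) - length) // 3 + 1))
                frag = plus[start : start + length]
                seq = frag if cls == "plus_homologous" else reverse_complement(frag)
            elif cls == "de_novo":
                seq = _de_novo_sequence(rng, length, spec.gc_target)
            else:
                seq = "".join("ACGU"[j] for j in rng.integers(0, 4, size=length))
            records.append(
                PoolRecord(
                    id=f"s{idx:06d}",
                    sequence=seq,
                    weight=1.0,
                    cycle=spec.cycle_index,
                    lane_intensity=spec.lane_intensity,
                    label=cls,
                )
            )
            idx += 1
    order = rng.permutation(len(records))
    return SequencePool(records=[records[i] for i in order])


def gen_delay_series(
    k: float,
    s0: float,
    delays,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Delay series of free-strand fractions for rate-fit recovery.

    Noiseless values follow the equal-strand second-order closed form
    1/(1 + k*s0*delay); Gaussian noise of sd ``noise_sd`` is added, then
    clipped to [0, 1].  Columns: delay_min, fraction_free.
    """
    delays = np.asarray(delays, dtype=float)
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    if not (k > 0 and s0 > 0):
        raise ValueError("k and s0 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    clean = fraction_free(delays, AnnealingParams(k, s0, s0))
    clean = np.atleast_1d(np.asarray(clean, dtype=float))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return pd.DataFrame(
        {"delay_min": delays, "fraction_free": np.clip(clean, 0.0, 1.0)}
    )


def gen_amp_trajectory(
    r: float,
    protocol: CycleProtocol,
    plateau: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    c0: float = 1.0,
) -> pd.DataFrame:
    """Per-cycle copy trajectory: exponential growth capped at a plateau.

    Copies follow min(c0 * r**cycle, plateau) for cycles 0..n_cycles with
    multiplicative lognormal noise of log-sd ``noise_sd``; serial-dilution
    events are recorded per the protocol (copies are in cumulative,
    dilution-corrected units).  Columns: cycle, copies, diluted_after.
    """
    if not r > 0:
        raise ValueError("r must be positive")
    if not plateau > c0:
        raise ValueError("plateau must exceed the starting copy number")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    cycles = np.arange(protocol.n_cycles + 1)
    copies = np.minimum(c0 * np.power(float(r), cycles), plateau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        copies = copies * np.exp(rng.normal(0.0, noise_sd, size=copies.shape))
    diluted = (
        (cycles > 0)
        & (protocol.dilution_interval > 0)
        & (cycles % max(protocol.dilution_interval, 1) == 0)
        & (protocol.dilution_fold > 1)
    )
    return pd.DataFrame(
        {"cycle": cycles, "copies": copies, "diluted_after": diluted}
    )
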