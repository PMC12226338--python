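"""Bookkeeping and inference for pH/freeze-thaw RNA replication cycles.

Each replication cycle denatures duplexes by adding HCl, neutralises with
KOH, and polymerises in the eutectic brine phase of water-ice.  The
acid/base switching deposits KCl into the reaction; serial dilution into
KCl-free mix resets the ionic strength.  Freezing concentrates solutes
into the eutectic phase by a calibrated linear factor.  Amplification is
accounted for as band-intensity fold-change times the cumulative dilution
between sampling points, and growth is fitted as log-linear over the
pre-plateau window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EutecticCalibration",
    "CycleProtocol",
    "AmplificationFit",
    "kcl_increment",
    "kcl_trajectory",
    "eutectic_factor",
    "eutectic_concentration",
    "cumulative_dilution",
    "effective_amplification",
    "per_cycle_exponent",
    "fit_growth",
    "triplet_consumption",
    "yield_from_gel",
]


@dataclass(frozen=True)
class EutecticCalibration:
    """Calibration of the freeze-concentration factor.

    ``preconc_fold`` is the pre-concentration applied to the buffer before
    the calibration series; ``transition_fold`` is the fold at which the
    concentrated sample no longer retains an ice phase at the working
    temperature.  The overall concentration factor is their product: a
    50x pre-concentrated replication buffer whose ice phase vanishes at
    8.8x implies a 440-fold enrichment of solutes in the eutectic phase.
    """

    preconc_fold: float = 1.0
    transition_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.preconc_fold < 1 or self.transition_fold < 1:
            raise ValueError("calibration folds must be >= 1")


@dataclass(frozen=True)
class CycleProtocol:
    """A pH/freeze-thaw cycling protocol.

    Volumes in µl, molarities in mol/L, KCl in mM.  ``dilution_interval``
    of 0 means no serial dilution; otherwise the reaction is diluted
    ``dilution_fold``-fold after sampling at every multiple of the
    interval.
    """

    n_cycles: int
    v_reaction: float = 125.0
    v_acid: float = 0.75
    m_acid: float = 0.1
    v_base: float = 0.75
    m_base: float = 0.1
    kcl0: float = 1.8
    dilution_fold: float = 1.0
    dilution_interval: int = 0
    eutectic: EutecticCalibration = field(default_factory=EutecticCalibration)

    def __post_init__(self) -> None:
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be non-negative")
        for name in ("v_reaction", "v_acid", "m_acid", "v_base", "m_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kcl0 < 0:
            raise ValueError("kcl0 must be non-negative")
        if self.dilution_fold < 1:
            raise ValueError("dilution_fold must be >= 1")
        if self.dilution_interval < 0:
            raise ValueError("dilution_interval must be >= 0")


@dataclass(frozen=True)
class AmplificationFit:
    """Log-linear growth fit: copies = c0 * exp(b * cycle).

    ``fold_per_cycle`` is derived as exp(growth_exponent) so the two views
    can never disagree.
    """

    growth_exponent: float
    r_squared: float
    window: tuple[int, int]

    @property
    def fold_per_cycle(self) -> float:
        return math.exp(self.growth_exponent)


def kcl_increment(protocol: CycleProtocol) -> float:
    """KCl added per cycle, mM, from neutralising the acid spike.

    Uses the nominal reaction volume (the per-cycle 2x0.75 µl volume
    growth is ignored): 0.75 µl of 0.1 M HCl into 125 µl gives +0.6 mM.
    """
    return protocol.v_acid * protocol.m_acid / protocol.v_reaction * 1000.0


def kcl_trajectory(protocol: CycleProtocol) -> pd.DataFrame:
    """Per-cycle KCl concentrations.

    Returns one row per cycle 1..n_cycles with ``kcl_mM`` the
    concentration at the sampling point of that cycle (after that cycle's
    acid/base addition), ``diluted_after`` whether a serial dilution
    follows, and ``kcl_out_mM`` the concentration entering the next cycle.
    The diluent carries no KCl, so dilution divides by the dilution fold.
    """
    inc = kcl_increment(protocol)
    rows = []
    current = protocol.kcl0
    for cycle in range(1, protocol.n_cycles + 1):
        sampled = current + inc
        diluted = (
            protocol.dilution_interval > 0
            and cycle % protocol.dilution_interval == 0
            and protocol.dilution_fold > 1
        )
        out = sampled / protocol.dilution_fold if diluted else sampled
        rows.append((cycle, sampled, diluted, out))
        current = out
    return pd.DataFrame(
        rows, columns=["cycle", "kcl_mM", "diluted_after", "kcl_out_mM"]
    )


def eutectic_factor(cal: EutecticCalibration) -> float:
    """Overall eutectic concentration factor (preconc x transition)."""
    return cal.preconc_fold * cal.transition_fold


def eutectic_concentration(bulk: float, cal: EutecticCalibration) -> float:
    """Concentration in the eutectic phase given a bulk concentration.

    Unit-preserving: 4 (nM) with a 440-fold calibration gives 1760 (nM).
    """
    if bulk < 0:
        raise ValueError("bulk concentration must be non-negative")
    return bulk * eutectic_factor(cal)


def cumulative_dilution(
    protocol: CycleProtocol, from_cycle: int, to_cycle: int
) -> float:
    """Cumulative fold dilution between two sampling points.

    Samples are taken before dilution at each interval, so only dilution
    events strictly between the two sampling points count: multiples of
    the interval m with from_cycle <= m < to_cycle.  Three-fold dilution
    every five cycles from the cycle-5 sample to the cycle-40 sample spans
    seven events (after cycles 5, 10, ..., 35): 3**7 = 2187.
    """
    if from_cycle > to_cycle:
        raise ValueError("from_cycle must not exceed to_cycle")
    if protocol.dilution_interval <= 0 or protocol.dilution_fold == 1:
        return 1.0
    step = protocol.dilution_interval
    first = max(step, step * math.ceil(from_cycle / step))
    n_events = max(0, (to_cycle - 1 - first) // step + 1) if first < to_cycle else 0
    return float(protocol.dilution_fold) ** n_events


def effective_amplification(intensity_ratio: float, dilution: float) -> float:
    """Overall fold amplification: band-intensity fold times dilution fold."""
    if intensity_ratio < 0 or dilution < 0:
        raise ValueError("folds must be non-negative")
    return intensity_ratio * dilution


def per_cycle_exponent(total_fold: float, n_cycles: int) -> float:
    """Apparent per-cycle amplification: total_fold ** (1/n_cycles)."""
    if not total_fold > 0:
        raise ValueError("total_fold must be positive")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    return total_fold ** (1.0 / n_cycles)


def _coerce_trajectory(trajectory):
    if hasattr(trajectory, "columns"):
        cycles = np.asarray(trajectory["cycle"], dtype=float)
        copies = np.asarray(trajectory["copies"], dtype=float)
    else:
        cycles, copies = trajectory
        cycles = np.asarray(cycles, dtype=float)
        copies = np.asarray(copies, dtype=float)
    order = np.argsort(cycles)
    return cycles[order], copies[order]


def fit_growth(trajectory, window: tuple[int, int] | None = None) -> AmplificationFit:
    """Fit exponential growth over the pre-plateau window.

    Ordinary least squares of ln(copies) on cycle index.  ``window`` is an
    inclusive (first_cycle, last_cycle) override.  The auto-detected
    window is the longest initial run of cycles whose log-copies increase
    and whose point-wise increase exceeds 10% of the first increment; if
    that run holds fewer than 3 points (e.g. a flat trajectory) all points
    are used.
    """
    cycles, copies = _coerce_trajectory(trajectory)
    if window is not None:
        lo, hi = window
        sel = (cycles >= lo) & (cycles <= hi)
        cycles, copies = cycles[sel], copies[sel]
    if cycles.size < 3:
        raise ValueError("need at least 3 points in the fitting window")
    if np.any(copies <= 0):
        raise ValueError("copies must be positive within the fitting window")
    logc = np.log(copies)
    if window is None:
        d = np.diff(logc)
        j = 0
        if d.size and d[0] > 0:
            thr = 0.1 * d[0]
            while j < d.size and d[j] > 0 and d[j] > thr:
                j += 1
        if j + 1 >= 3:
            cycles, logc = cycles[: j + 1], logc[: j + 1]
    slope, intercept = np.polyfit(cycles, logc, 1)
    resid = logc - (slope * cycles + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((logc - logc.mean()) ** 2).sum())
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    return AmplificationFit(
        growth_exponent=float(slope),
        r_squared=min(max(r2, 0.0), 1.0),
        window=(int(cycles[0]), int(cycles[-1])),
    )


def triplet_consumption(product_table, supply: float) -> float:
    """Percent of the replenished triplet supply built into products.

    ``product_table`` has columns ``length_nt`` and ``yield`` (molar, same
    unit as ``supply``).  Each product of length L contributes
    floor(L / 3) triplets (non-triplet-register lengths arise from the
    terminal pentamer substrate).
    """
    if not supply > 0:
        raise ValueError("supply must be positive")
    if hasattr(product_table, "columns"):
        lengths = np.asarray(product_table["length_nt"], dtype=float)
        yields = np.asarray(product_table["yield"], dtype=float)
    else:
        lengths, yields = product_table
        lengths = np.asarray(lengths, dtype=float)
        yields = np.asarray(yields, dtype=float)
    if lengths.size == 0:
        return 0.0
    triplets = np.floor(lengths / 3.0)
    return float(100.0 * (yields * triplets).sum() / supply)


def yield_from_gel(
    band_intensity: float,
    band_length: float,
    ref_intensity: float,
    ref_length: float,
    ref_amount: float,
) -> float:
    """Molar yield of a band from stain densitometry.

    Intercalating-dye fluorescence is treated as proportional to RNA
    length, so molar amount scales as intensity per nucleotide relative to
    a reference band of known amount.
    """
    if min(band_intensity, band_length, ref_length, ref_amount) <= 0:
        raise ValueError("band and reference quantities must be positive")
    if ref_intensity <= 0:
        raise ValueError("reference intensity must be positive")
    return ref_amount * (band_intensity / band_length) / (ref_intensity / ref_length)
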