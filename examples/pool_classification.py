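"""Classify an emergent sequence pool against a ribozyme reference.

Builds a synthetic pool mixing ribozyme-homologous fragments with de novo
and random sequences, classifies every record by exact longest-common-
substring matching, and reports class proportions, homology footprints
and composition statistics.
"""

import numpy as np

from tripletrep.pools import (
    class_proportions,
    classify_pool,
    composition_stats,
    map_sites,
    uniqueness_fraction,
)
from tripletrep.simulate import PoolGenSpec, gen_emergent_pool, gen_reference

ref = gen_reference(seed=7, lengths=(180, 90), gc=0.6)
spec = PoolGenSpec(
    seed=11, n_sequences=1000, cycle_index=73,
    class_weights=(0.5, 0.2, 0.2, 0.1),  # minus / plus / de novo / junk
    length_range_nt=(12, 27),
)
pool = gen_emergent_pool(ref, spec)

table = class_proportions(pool, ref, min_match=12, length_band=(9, 27))
print("class proportions at cycle 73 (truth 0.5 / 0.2 / 0.3 incl. junk):")
print(table.round(3).to_string())
# minus_homologous fragments dominate early self-copying; de novo and junk
# sequences carry no >=12-nt exact match and land in no_homology.

hist = map_sites(pool, ref, min_match=12, seed=1)
for (subunit, strand), arr in sorted(hist.items()):
    if arr.sum() > 0:
        peak = int(np.argmax(arr))
        print(f"{subunit}({strand}): footprint mass {arr.sum():,.0f}, "
              f"peak coverage at position {peak}")
# Multi-mapping records are randomly assigned to one site (seeded), so
# total footprint mass is conserved across seeds.

no_hom = [c.id for c in classify_pool(pool, ref) if c.label == "no_homology"]
for rec in pool:
    if rec.id in set(no_hom):
        rec.label = "no_homology"
stats = composition_stats(pool, labels={"no_homology"})
print(f"no-homology class: GC = {stats.gc_fraction:.2f}, "
      f"G/C = {stats.g_to_c_ratio:.2f}, A/U = {stats.a_to_u_ratio:.2f}")
print(f"pool uniqueness: {uniqueness_fraction(pool):.2f}")
# G/C and A/U near 1 (Chargaff balance) indicate templated synthesis of
# the de novo class rather than untemplated base preference.
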