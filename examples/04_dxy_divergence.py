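"""Jukes-Cantor-corrected D_XY between two gene-order haplotype groups.

Simulates two 2-individual groups of 10-kb concatenated coding sequence
whose planted between-group divergence is 0.024 substitutions/site — the
shallow timescale over which one gene-order class lost its duplicates —
and recovers the planted value.
"""

import numpy as np

from mitodrl import dxy
from mitodrl.drl_simulator import evolve_jc_groups

rng = np.random.default_rng(4)
group_a, group_b = evolve_jc_groups(
    length=10_000, d_between=0.024, d_within=0.002, n_per_group=2, rng=rng
)
est = dxy(group_a, group_b)
print(f"between-group pairs: {est.n_pairs}, comparable sites/pair >= {est.n_sites_min}")
print(f"mean p-distance: {est.p_mean:.4f}")
print(f"D_XY (JC-corrected): {est.d_xy:.4f}")
# D_XY is close to the planted 0.024: all duplicate-gene loss in this
# history happened within ~2.4% sequence divergence.
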