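"""Scan a synthetic mt genome for NUMT-like nuclear matches and pick ddPCR targets.

Plants one exact and one 5-mismatch nuclear copy of mitochondrial windows,
profiles the whole circle, and selects regions far from any nuclear match.
"""

from ccfmtdna.numtscan import numt_profile, select_target_regions
from ccfmtdna.synthdata import NumtPlan, make_genomes

# 4-kb circular mt genome, 30-kb nuclear genome, two planted NUMT copies
mt, nuclear = make_genomes(
    4000, 30000,
    numts=[NumtPlan(insert_position=5000, mt_window_center=800, n_mismatches=0),
           NumtPlan(insert_position=20000, mt_window_center=2500,
                    n_mismatches=5, revcomp=True)],
    seed=11,
)

profile = numt_profile(mt, nuclear, window=101)
print(f"profile over {len(profile)} positions; "
      f"d_min range {profile.d_min.min()}..{profile.d_min.max()}")
print(f"at the exact-NUMT centre (800):      d_min = {profile.value_at(800)}")
print(f"at the 5-mismatch NUMT centre (2500): d_min = {profile.value_at(2500)}")

regions = select_target_regions(profile, min_distance=20, min_length=150)
print(f"\n{len(regions)} NUMT-safe target regions (d_min >= 20, >= 150 bp):")
for r in regions[:5]:
    print(f"  [{r.start}, {r.end})  length {r.length}  min d_min {r.min_profile_value}")

# A d_min of 0 marks an exact nuclear copy (a probe there would count nuclear
# DNA as mitochondrial); high-d_min runs are safe placements for ddPCR probes.
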