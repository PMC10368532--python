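"""Arm-level copy-number profile, aneuploidy score, fCNA, ploidy and WGD.

Arm calls threshold the weighted mean exon log2 read-depth ratio at +/-0.2
after per-sample median centering; ploidy is read off a cellularity-ploidy
probability grid at the estimated purity, and WGD is called at ploidy >= 3.
"""

from mosaicevo import CohortConfig, karyotype_profile, simulate_cohort
from mosaicevo.genome import load_arms

arms = load_arms("mm10")
for wgd in (False, True):
    cfg = CohortConfig(n_mice=1, samples_per_mouse=1, purity=0.6, wgd=wgd, seed=11)
    s = simulate_cohort(cfg).samples[0]
    prof = karyotype_profile(s.sample, s.exon_ratios, arms, s.grid, s.purity,
                             baf_records=s.baf)
    altered = prof.arm_calls[prof.arm_calls["call"].isin(["gain", "loss"])]
    print(f"WGD simulated={wgd}: aneuploidy score {prof.aneuploidy_score}, "
          f"fCNA {prof.fcna:.3f}, ploidy {prof.ploidy:.1f}, "
          f"WGD called={prof.wgd}, allelic imbalance {prof.allelic_imbalance:.3f}")
    for arm, row in altered.iterrows():
        print(f"  {arm}: {row['call']} (mean log2 {row['mean_log2']:+.2f})")
# chr5 gain and chr12/chr16 loss are the simulated truth; fCNA is their
# length share of the genome
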