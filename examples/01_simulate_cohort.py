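"""Simulate a small tumor cohort and look at its ground truth.

Each mouse carries a truncal mutation trunk shared by all of its samples,
private mutations per sample, recurrent arm events (chr5 gain, chr12 and
chr16 loss) and sgRNA cut-site editing. Everything downstream is estimated
from these data and can be checked against the truth kept in the bundle.
"""

from mosaicevo import CohortConfig, expected_vaf, simulate_cohort

config = CohortConfig(n_mice=2, samples_per_mouse=3, purity=0.7, seed=7)
bundle = simulate_cohort(config)

print(f"mice: {len(bundle.mice)}, tumor samples: {len(bundle.samples)}")
m = bundle.mice[0]
print(f"{m.mouse}: {len(m.truth.truncal_keys)} truncal mutations, "
      f"{sum(len(k) for k in m.truth.private_keys.values())} private, "
      f"ploidy {m.truth.ploidy:.2f}, WGD={m.truth.wgd}")

# a clonal heterozygous mutation on a diploid region at purity 0.7 is
# expected at VAF 0.7/2 = 0.35; the simulated calls should scatter around it
s = m.samples[0]
snvs = [v for v in s.variants if v.variant_class == "SNV"]
mean_vaf = sum(v.tumor_alt / v.tumor_depth for v in snvs) / len(snvs)
print(f"{s.sample}: {len(s.variants)} variants, mean SNV VAF {mean_vaf:.3f} "
      f"(diploid-region expectation {expected_vaf(0.7, 2):.3f})")
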