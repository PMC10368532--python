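"""Somatic filtering, driver-region exclusion and the trinucleotide spectrum.

The murine profile demands tumor coverage >20x, normal coverage >10x and
VAF >= 0.1; indels also pass a tandem-repeat screen on the 20 nt downstream,
and anything in an sgRNA-targeted window (padded 50 bp) is removed as an
engineered driver. Surviving SNVs are deduplicated per mouse and summarized
over the 96 pyrimidine-context classes.
"""

from mosaicevo import (
    CohortConfig, MURINE, apply_filter, exclude_sgrna_regions, mutational_burden,
    repeat_filter, simulate_cohort, trinuc_spectrum,
)

bundle = simulate_cohort(CohortConfig(n_mice=2, samples_per_mouse=2, seed=3))
filtered = {}
for s in bundle.samples:
    res = apply_filter(s.variants, MURINE)
    kept = [v for v in res.kept
            if v.downstream_20nt is None or repeat_filter(v.downstream_20nt)]
    kept = exclude_sgrna_regions(kept, bundle.target_regions, pad=50)
    filtered[s.sample] = kept
    print(f"{s.sample}: {len(s.variants)} called -> {len(kept)} kept "
          f"(rejections: {dict(res.reasons)})")

# burden: exonic mutations per callable megabase (here a nominal 50 Mb exome)
n_exonic = sum(1 for v in filtered[bundle.samples[0].sample] if v.exonic)
print(f"burden: {mutational_burden(n_exonic, 50):.2f} mutations/Mb over 50 Mb")

mouse_of = {s.sample: s.mouse for s in bundle.samples}
spec = trinuc_spectrum(
    [(s, v) for s, kept in filtered.items() for v in kept], mouse_of
)["ALL"]
top = spec.frequencies.sort_values(ascending=False).head(3)
print(f"spectrum over {spec.total} unique per-mouse mutations; top classes:")
for cls, f in top.items():
    print(f"  {cls}: {f:.3f}")  # C>T classes dominate under the default mix
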