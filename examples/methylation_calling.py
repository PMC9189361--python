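"""Simulate a bisulfite amplicon experiment and call the methylation rate.

Builds a 2 kb promoter with three CpG islands, simulates 200 plus-strand
bisulfite reads over the first island with every CpG site methylated at
probability 0.7, aligns them against the converted reference and reports
the pooled region methylation rate r_m (methylated calls / informative
calls), which should sit near the generating probability.
"""

from methmorph import (
    PromoterSpec,
    ReadSimParams,
    call_sample,
    generate_promoter,
    simulate_bisulfite_reads,
    uniform_profile,
)

promoter = generate_promoter(PromoterSpec(seed=0))
print(f"promoter: {len(promoter)} bp, {len(promoter.cpg_sites)} CpG sites")
print(f"islands (0-based half-open): {promoter.islands}")

a, b = promoter.islands[0]
amplicon = promoter.subregion(a - 20, min(b, a + 220) + 20, name="island1_amplicon")
profile = uniform_profile(amplicon, 0.7)
reads = simulate_bisulfite_reads(amplicon, profile, ReadSimParams(depth=200, seed=1))
table = call_sample(amplicon, [(rid, seq) for rid, seq, _ in reads])

print(f"amplicon: {len(amplicon)} bp with {len(amplicon.cpg_sites)} CpG sites, depth 200")
print(table.site_counts().head(5).to_string(index=False))
print(f"pooled r_m = {table.region_rate():.4f} (generating probability 0.7)")
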