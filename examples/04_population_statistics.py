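"""Per-individual density, frequency-spectrum and frameshift statistics.

Every statistic follows the same recipe: compute per individual over
that individual's called variants, then average across individuals.
"""

from exindel.pipeline import run_pipeline
from exindel.popstats import AF_BIN_EDGES

result = run_pipeline(seed=1)
stats = result.stats

print(f"analyzed region: {stats['region_mb']:.2f} Mb of exome targets")
print(f"INDEL density:   {stats['indel_density_per_mb']:.2f} per Mb "
      "per individual")
print(f"INDELs/exome:    {stats['indels_per_exome']:.1f}")
print(f"heterozygous:    {stats['pct_heterozygous']:.1f}% of an "
      "individual's calls")
print(f"frameshift:      {stats['pct_frameshift_per_exome']:.1f}% of an "
      "individual's calls (length not a multiple of 3)")
print(f"del:ins ratio:   {stats['deletion_insertion_ratio']:.2f}")
print(f"rare (AAF<=1%):  {stats['pct_rare']:.1f}% of loci")

print("\ndensity across the 7 allele-frequency bins (variants/Mb):")
for b, density in enumerate(stats["density_by_af_bin"]):
    lo, hi = AF_BIN_EDGES[b], AF_BIN_EDGES[b + 1]
    print(f"  ({100 * lo:6.2f}%, {100 * hi:6.2f}%]  {density:7.3f}")
print("the per-bin densities sum exactly to the total density "
      "(the bins partition (0, 1])")
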