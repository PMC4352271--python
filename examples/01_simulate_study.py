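"""Generate a synthetic exome INDEL study and inspect its ground truth.

Builds a 1 Mb reference with planted repeat tracts, exome-like target
intervals, a 50-sample truth call set with a rare-skewed frequency
spectrum, and three caller call sets with distinct error profiles.
"""

import numpy as np

from exindel.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(), seed=1)

truth = study.truth
print(f"reference: {study.reference.length('1'):,} bp on contig 1")
print(f"targets:   {study.targets.total_bp():,} bp in "
      f"{len(study.targets.intervals())} intervals")
print(f"truth:     {truth.n_loci:,} INDEL loci x {truth.n_samples} samples")
print(f"planted slippage (CCC) fraction: {study.truth_ccc_flags.mean():.3f}")

lengths = np.array([r.length for r in truth.loci])
print(f"deletions : insertions = {(lengths < 0).sum()} : {(lengths > 0).sum()}")
singletons = (truth.genotypes.sum(axis=1) == 1).mean()
print(f"singleton sites: {100 * singletons:.1f}% (rare-skewed spectrum)")

for caller, raw in study.raw_callsets.items():
    print(f"{caller}: {len(raw):,} raw records "
          "(some right-shifted or complex on purpose)")
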