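"""From raw pooled read counts to a clean allele-frequency matrix.

Simulates a small pool-seq panel, writes it in the sync dialect, parses
it back, applies the cleaning rules (zero counts below 8, keep
polymorphic bi-allelic loci with dataset-wide MAF >= 5%) and converts
to frequencies.
"""

import tempfile
from pathlib import Path

from poolclover.counts_io import (
    filter_loci, parse_counts, to_frequencies, write_counts, zero_low_counts,
)
from poolclover.synthetic import SimulationConfig, simulate_metapop, simulate_pool_reads

cfg = SimulationConfig(n_pops=12, n_loci=120, seed=42)
truth = simulate_metapop(cfg)
rcm = simulate_pool_reads(truth)

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "counts.sync"
    write_counts(rcm, path, format="sync")
    rcm = parse_counts(path, format="sync", accessions=rcm.accessions)

rcm = zero_low_counts(rcm, min_count=8)
rcm, report = filter_loci(rcm, maf_min=0.05)
afm = to_frequencies(rcm)

print(f"loci in: {report['n_input']}, retained: {report['n_retained']}")
for rule, ids in report["dropped"].items():
    print(f"  dropped ({rule}): {len(ids)}")
print(f"frequency matrix: {afm.freq.shape[0]} pools x {afm.freq.shape[1]} loci, "
      f"{afm.missing.mean():.1%} missing cells")
print(afm.to_frame().iloc[:3, :4].round(3))
# Each entry is the alternate-allele frequency of one pool of 10 plants
# estimated from ~500x read counts; missing cells had no surviving reads.
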