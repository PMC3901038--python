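"""Design unstructured three-letter hybridization probes.

Targets are random 19-mers over {A, U, C}: with no G the target cannot form
Watson-Crick G-C self-structure, and the DNA probes (reverse complement over
{A, T, G}) cannot either, so hybridization is not rate-limited by secondary
structure.  Candidates are filtered for balanced base composition
(GC fraction 0.4-0.6, i.e. 8-11 C residues) and for sequence non-redundancy
(LZ76 complexity >= 9, at or above the typical complexity of natural exon
19-mers), then ranked.
"""

from fastfish import DesignConfig, design_probes, lz_complexity
from fastfish.complexity import complexity_stats
from fastfish.design import pairing_proxy

config = DesignConfig(n_samples=20_000, seed=42)
pairs = design_probes(config)

print(f"{len(pairs)} candidate pairs survive the filters\n")
print("rank  target (RNA 5'->3')      probe (DNA 5'->3')       LZ  self-pairs")
for rank, (target, probe) in enumerate(pairs[:5], start=1):
    print(
        f"{rank:>4}  {target.sequence}      {probe.sequence}  "
        f"{target.lz_complexity:>2}  {pairing_proxy(target.sequence):>6}"
    )

stats = complexity_stats([t for t, _ in pairs])
print(f"\nretained complexity: mean {stats.mean:.2f} +- {stats.sd:.2f} (n={stats.n})")
print(f"calibration: all-distinct 19-mer -> {lz_complexity('abcdefghijklmnopqrs')}, "
      f"A*19 -> {lz_complexity('A' * 19)}")
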