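"""Scan a sex-linked SSR for sex-specific alleles in a dioecious crop.

The simulator plants one male-transmitted allele at the sex-linked marker;
the scan reports every allele confined to one sex, with carrier counts and
the gene pool(s) it occurs in.
"""

from hopfinger.panel_qc import sex_specific_alleles
from hopfinger.synthetic import SimConfig, simulate_dataset

cfg = SimConfig(seed=31, n_cult=80, n_wna=40, clone_groups=(),
                null_freqs=(0.0,) * 9, sex_ratio=0.3)
ds = simulate_dataset(cfg)
marker, planted = ds.truth.sex_allele

rep = sex_specific_alleles(ds.ssr, marker)
print(f"sex-linked marker {marker}; planted male allele: {planted} bp\n")
print("male-specific alleles (carried by males only):")
for allele, n in rep.male_specific.items():
    tag = " <- planted" if allele == planted else ""
    print(f"  {allele} bp: {n} carriers, pool {rep.pools[allele]}{tag}")
print("female-specific alleles (absent from every male):")
for allele, n in rep.female_specific.items():
    print(f"  {allele} bp: {n} carriers, pool {rep.pools[allele]}")
print("\n(an allele seen in even one individual of the other sex is not "
      "reported; female-specific alleles here arise by drift, not planting)")
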