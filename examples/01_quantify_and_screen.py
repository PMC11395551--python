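"""Quantify a study and screen for key aroma compounds.

Builds the deterministic study-shaped dataset (four ferments S1–S4 × 3
replicates, 99 volatiles), applies internal-standard quantitation and the
rOAV / GC-O screens, and prints the Venn regions. The "key" compounds
are those clearing rOAV >= 1 in every ferment *and* reaching GC-O panel
consensus — the compounds a recombination experiment would start from.
"""

import aromakey as ak

bundle, truth = ak.paper_fixture()
result = ak.run_pipeline(bundle)

print("rOAV >= 1 per ferment:",
      {s: len(v) for s, v in sorted(result.key_set.per_sample_roav_pass.items())})
print("Venn regions:", result.key_set.venn_counts())
print("key aroma compounds:")
for name in sorted(result.key_set.members):
    print("   ", name)
print()
print("Counts mirror the study design: 15 compounds pass rOAV in every "
      "ferment, 17 reach GC-O consensus, and their 12-member overlap is "
      "the key aroma set.")
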