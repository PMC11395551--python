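"""Fisher-LSD letters, class totals and the sample dendrogram.

Prints the per-ferment chemical-class totals with percent change vs the
wild-type ferment, the ANOVA-LSD compact letter display for two key
compounds, and the k=2 hierarchical clustering of the ferments.
"""

import aromakey as ak

bundle, truth = ak.paper_fixture()
result = ak.run_pipeline(bundle)

print("class totals (µg/kg) and % change vs S1:")
ct = result.class_totals
for cls in ("pyrazine", "ketone", "acid", "grand_total"):
    sub = ct[ct.chem_class == cls]
    row = ", ".join(f"{r.sample_id}={r.total:7.0f} ({r.pct_change_vs_reference:+5.1f}%)"
                    for r in sub.itertuples())
    print(f"   {cls:12s} {row}")

print("\nFisher-LSD letters (groups sharing a letter do not differ at "
      "alpha = 0.05):")
letters = result.anova_letters
for compound in ("2,3,5,6-tetramethylpyrazine", "guaiacol"):
    sub = letters[letters.compound_name == compound]
    row = ", ".join(f"{r.sample_id}: {r.mean:.3f} µg/g '{r.letters}'"
                    for r in sub.itertuples())
    print(f"   {compound}: {row}")

print("\nsample clustering (k=2):", result.sample_clusters)
print("dendrogram:", result.sample_dendrogram)
print("\nThe double-knockout ferment S4 separates from S1–S3, matching "
      "its planted stronger aroma shift.")
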