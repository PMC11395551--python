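"""Generate a fresh seeded study and score recovery against the truth.

Every dataset carries its planted ground truth (true concentrations, the
intended key-compound set, VIP markers and sample partition), so any
change to the analysis can be scored as set precision/recall and a Rand
index instead of eyeballing plots.
"""

import aromakey as ak
from aromakey.synthetic_data import SimulationDesign, truth_report

design = SimulationDesign(seed=7)
bundle, truth = ak.generate_dataset(design)
result = ak.run_pipeline(bundle)

report = truth_report(
    truth,
    recovered_key_set=set(result.key_set.members),
    recovered_vip=set(result.vip[result.vip > 1].index),
    recovered_partition=result.sample_clusters,
)
print("key-set recovery:", report["key_set"])
print("VIP-marker recovery:", report["vip_markers"])
print("cluster Rand index:", report["cluster_rand_index"])
print("\nPrecision/recall of 1.0 and Rand index 1.0 mean the pipeline "
      "recovered exactly the planted structure from noisy peak tables.")
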