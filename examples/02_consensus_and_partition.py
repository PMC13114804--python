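"""Cross-cohort consensus rules and the disease-specific partition.

Generates the default synthetic two-disease study (known ground truth),
derives a strict-intersection consensus for the well-powered disease and a
vote-based consensus for the disease with a weak cohort, then partitions
the two signatures into specific / shared-concordant / shared-discordant
sets and reports how much of the planted truth each rule recovered.
"""

from mirsig.consensus import (partition_signatures, strict_intersection,
                              vote_consensus)
from mirsig.synthetic_data import (consensus_recovery, default_spec,
                                   generate_study)

study = generate_study(default_spec(seed=1))

cll = strict_intersection(*study.tables["CLL"])
mm = vote_consensus(*study.tables["MM"])
for name, sig in (("CLL (strict)", cll), ("MM (vote)", mm)):
    rec = consensus_recovery(sig, study.truth, sig.disease)
    print(f"{name}: {len(sig)} consensus genes | "
          f"precision {rec['precision']:.3f}, recall {rec['recall']:.3f} "
          f"vs the planted program of {int(rec['n_true'])}")

partition = partition_signatures(cll, mm)
print("\nPartition:", partition.sizes())
print("Shared discordant genes (opposite direction in the two diseases):")
for sym, (d_cll, d_mm) in sorted(partition.shared_discordant.items()):
    print(f"  {sym}: CLL {d_cll} / MM {d_mm}")
print("\nThe strict rule recovers the concordant program almost exactly; "
      "the vote rule trades precision for recall where one cohort is weak.")
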