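"""Predict the protein consequence of the HES7 c.126delG deletion.

Applies the single-base deletion to a transcript with the canine HES7
geometry (synthetic stand-in sequence, 675-nt CDS / 224-aa protein),
re-translates, names the frameshift in HGVS style, applies the 50-nt
rule for nonsense-mediated decay, and classifies the two functional
domains of the repressor.
"""

from scdmap.consequence import (
    apply_cdna_variant,
    describe_consequence,
    domain_disruption,
    predict_nmd,
    translate,
)
from scdmap.worked_example import HES7_EDIT, hes7_domains, hes7_synthetic_transcript

t = hes7_synthetic_transcript()
wt_protein, _ = translate(t.cds)
print(f"wild-type protein: {len(wt_protein)} residues")

mut_cds = apply_cdna_variant(t, HES7_EDIT)
mut_protein, terminated = translate(mut_cds)
result = describe_consequence(wt_protein, mut_protein, terminated)
print(f"{HES7_EDIT} -> {result.hgvs_p}")
print(f"  frameshift from residue {result.first_altered} "
      f"({wt_protein[result.first_altered - 1]} -> "
      f"{mut_protein[result.first_altered - 1]}), "
      f"stop in place of residue {result.stop_residue}, "
      f"mutant length {result.mutant_length} aa")

# NMD: position of the new stop in mutant mRNA coordinates
stop_mrna = t.cds_start - 1 + 3 * result.stop_residue - 2
nmd = predict_nmd(t, stop_mrna)
print(f"  NMD 50-nt rule: {nmd.verdict} "
      f"(PTC {nmd.distance_to_final_junction} nt upstream of the final junction)")

for name, status in domain_disruption(result, hes7_domains()).items():
    print(f"  domain {name}: {status}")
print("A repressor missing its Orange domain and half its DNA-binding "
      "domain cannot sustain the segmentation-clock autorepression loop.")
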