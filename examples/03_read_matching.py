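"""The three matching modes on a toy reference.

Exact multi-hit search (zero mismatches, both strands), best-stratum
search (all 0-mismatch hits if any, else all 1-mismatch hits), and
Smith-Waterman rescue with identity/coverage thresholds.
"""

from aquasrna.io_formats import ReferenceSet
from aquasrna.matcher import build_index, local_align_rescue, map_exact, map_one_mismatch

ref = ReferenceSet(
    "toy", "genome",
    (("chr1", "TTACGTACGTAGGCTGACTGACCGTAGGCATCGATCGTACGGATCCGTA"),),
)
index = build_index(ref)

query = "ACGTACGTAGGCTGACTGAC"  # exact 20-mer from chr1
for hit in map_exact(query, index):
    print(f"exact: {hit.ref_id}:{hit.start} strand {hit.strand} mismatches {hit.mismatches}")

variant = "ACGTACGTAGGATGACTGAC"  # one substitution
for hit in map_one_mismatch(variant, index):
    print(f"best stratum: {hit.ref_id}:{hit.start} mismatches {hit.mismatches}")
# The 1-mismatch hit is reported only because no 0-mismatch locus
# exists; with both present, only the 0-mismatch stratum is returned.

rescue_ref = ReferenceSet("rescue", "rrna_rescue", (("rRNA_28S_fragment", ref.records[0][1]),))
degraded = "ACGTACGTAGGATGACTGACCGTAGGCAT"  # 29 nt, 1 internal mismatch
hit = local_align_rescue(degraded, rescue_ref, min_identity=0.85, min_coverage=0.8)
print(f"rescue: {hit.ref_id} identity {hit.identity:.3f} coverage {hit.coverage:.2f} score {hit.score}")
# identity is over aligned columns, coverage over the read; both must
# clear their thresholds for a fragment to be re-annotated as rRNA.
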