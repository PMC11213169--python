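"""Classify deletion junctions: non-templated nucleotides, microhomology,
or blunt joins.

Non-templated nucleotides (NTN) at junctions — bases explained by neither
flank's reference continuation — are a hallmark of RAG cleavage repaired by
NHEJ with TdT.  Microhomology is sequence shared by both flank ends,
assignable to either side.
"""
from ragdel.junctions import resolve_junction
from ragdel.models import DeletionCall

#           0         1         2         3
#           0123456789012345678901234567890123456789
reference = "TTTTTTTTAGCCCCCCCCCCAGTTTTTTTTTTGGGGGGGG"
genome = {"chr1": reference}

# flanks share the 2-base end "AG": ...TTAG | CCC...CCAG | TTT...
d = DeletionCall("P1", "chr1", 10, 22, junction_insert="", del_id="mh")
res = resolve_junction(d, genome)
print(f"empty insert, shared flank end -> {res.status}, mh_len={res.mh_len}")

# an insert matching nothing around the breakpoints is pure NTN
d = DeletionCall("P1", "chr1", 10, 30, junction_insert="GAG", del_id="ntn")
res = resolve_junction(d, genome)
print(f"untemplated insert           -> {res.status}, ntn='{res.ntn_seq}'")

# an insert equal to the reference past the left breakpoint is templated:
# it is stripped and the breakpoint re-normalised (shifted right)
d = DeletionCall("P1", "chr1", 10, 30, junction_insert=reference[10:14], del_id="tpl")
res = resolve_junction(d, genome)
print(f"fully templated insert       -> {res.status}; left breakpoint "
      f"re-assigned 10 -> {d.left_bp}")
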