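"""Blinding index from treatment-guess tables.

After the randomization procedure each patient guesses their assigned
arm on a five-level certainty scale.  The arm-specific index is
(correct - incorrect) / n: 0 under random guessing (ideal blinding),
1 under complete unblinding.
"""

from anginatrial import BlindingTable, blinding_index

# effective blinding: guesses split evenly, many "don't know"
blinded = BlindingTable(correct_sure=15, correct_unsure=16, dont_know=88,
                        incorrect_unsure=17, incorrect_sure=14)
# partial unblinding: correct guesses dominate
unblinded = BlindingTable(correct_sure=52, correct_unsure=31, dont_know=45,
                          incorrect_unsure=12, incorrect_sure=10)

for label, table in (("blinded arm", blinded), ("unblinded arm", unblinded)):
    bi, lo, hi = blinding_index(table)
    print(f"{label:14s}: index {bi:+.2f} (95% CI {lo:+.2f} to {hi:+.2f}), n={table.n}")
# The first interval straddles 0 (blinding held); the second sits well
# above 0, the signature of patients working out their assignment.
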