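"""Decide which cathelicidin precursors encode an active peptide.

A functional precursor needs four cathelin-domain cysteines, a VRR/VTR-
like cleavage motif within ten residues of the fourth cysteine, and a
short, net-positive C-terminal peptide.  The three published Komodo
precursors are classified; two pass, one (VK-CATH2) fails on the motif
and charge rules.
"""
from ampminer import data, classify_precursor

for rec in data.load_cathelicidin_precursors():
    v = classify_precursor(rec)
    failed = [name for name, ok in v.reasons if not ok]
    print(f"{rec.id:24s} accepted={v.accepted}")
    if v.accepted:
        print(f"   mature peptide ({v.cterm_length} aa, "
              f"charge {v.cterm_charge_int:+d}): {v.cterm_peptide}")
    else:
        print(f"   failed rules: {', '.join(failed)}")
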