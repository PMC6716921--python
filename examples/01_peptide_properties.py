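"""Compute the physicochemical profile of published defensin peptides.

Loads the packaged Komodo dragon β-defensin repertoire and prints the
property row (length, average MW, pepstats-style half-integer charge,
isoelectric point) for a few peptides.  Charge > 0 marks the cationic
character β-defensins need for membrane activity; the pI is the pH at
which the modeled net charge crosses zero.
"""
from ampminer import data, peptide_report

for name in ["VkBD1_VARKO", "VkBD54_VARKO", "VkBD36_VARKO"]:
    rec = next(r for r in data.load_beta_defensins() if r.id == name)
    row = peptide_report(rec.sequence, id=rec.id)
    print(f"{row.id:14s} len={row.length:3d}  MW={row.molecular_weight:8.2f}"
          f"  charge={row.charge_halfint:+5.1f}  pI={row.pI:7.4f}"
          f"  cys={row.cys_count}")
print("\nVkBD54 is strongly cationic (basic pI ~12); VkBD36 is one of the"
      "\nnine anionic outliers that are atypical for this peptide family.")
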