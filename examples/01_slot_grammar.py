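"""Enumerate the construct designs a backbone admits under the slot grammar.

The platform fixes five 30-nt overlap sites; a slot is a (left, right) site
pair, and a backbone whose termini carry sites i and j accepts exactly the
slot sequences whose sites tile i -> j.
"""

from gmapkit import Backbone, SITES, enumerate_fills, flanks_for_slot

for slot in ("pA", "gA", "pB", "gB", "pC", "gC"):
    left, right = flanks_for_slot(slot)
    print(f"{slot}: flanked by sites #{left.id} and #{right.id}")

print("\nSite #2 30-mer:", SITES[2].sequence, f"(embeds {SITES[2].encoded_enzyme})")

# A full-length backbone (termini sites 1 and 5) accepts three designs:
backbone = Backbone("lentiviral", "A" * 70, chain_start_site=1, chain_end_site=5)
print("\nDesigns tiling a 1-5 backbone (fewest fragments first):")
for fill in enumerate_fills(backbone):
    print("  " + ":".join(fill))
# pA:gC and pC:gB are the two-fragment routes; pA:gA:pB:gB is the
# four-fragment dual-expression design.
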