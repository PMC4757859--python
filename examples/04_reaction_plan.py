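"""Lay out an isothermal assembly reaction and size the colony screen.

Parts are normalized to 57 nM, so 1 uL delivers 5.7e-2 pmol; the reaction
is 15 uL master mix + 5 uL pooled inserts at 50 degC for 20 min.  The
number of colonies to screen comes from 1 - (1-p)^n > confidence, where p
is the per-colony probability of a correct assembly.
"""

from gmapkit import (
    ReactionDefaults,
    colonies_to_screen,
    make_flanked_part,
    reaction_plan,
    success_probability,
)
from gmapkit.reaction import ILLUSTRATIVE_EFFICIENCIES

promoter = make_flanked_part("ACGT" * 150, "pA", name="pGK")
gene = make_flanked_part("ACGT" * 250, "gC", name="GFP")
backbone = make_flanked_part("ACGT" * 500, "gB", name="LV-1-5")  # size carrier

plan = reaction_plan([promoter, gene], backbone,
                     ReactionDefaults(), ILLUSTRATIVE_EFFICIENCIES)
print(plan.to_tsv())
print(f"incubate {plan.incubation_temp:.0f} degC for {plan.incubation_min:.0f} min; "
      f"screen {plan.colonies_to_screen} colonies")

print("\ncolonies needed for >99% chance of a correct clone:")
for n_frag, p in ILLUSTRATIVE_EFFICIENCIES.values.items():
    n = colonies_to_screen(p, 0.99)
    print(f"  {n_frag} fragment(s), per-colony p={p:.2f}: screen {n} "
          f"(success {success_probability(p, n):.4f})")
# Two-fragment reactions need 3 colonies and four-fragment reactions 5 —
# the platform's rule of thumb.
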