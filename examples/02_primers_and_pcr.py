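"""Design overhang primers for a gene insert and simulate the PCR.

The forward primer is the slot's left site 30-mer plus template homology
grown until its nearest-neighbor Tm reaches the 62 degC annealing target;
the reverse primer carries the reverse complement of the right site.
"""

import random

from gmapkit import classify_fragment, design_part_primers, extension_time, simulate_pcr

rng = random.Random(42)
template = "".join(rng.choice("ACGT") for _ in range(900))  # a 900 bp ORF stand-in

pair = design_part_primers(template, slot="gB", name="myGene")
print(f"{pair.forward_name}: {pair.forward}")
print(f"  homology {len(pair.forward_homology)} nt, Tm {pair.homology_tm_fwd:.1f} degC")
print(f"{pair.reverse_name}: {pair.reverse}")
print(f"  homology {len(pair.reverse_homology)} nt, Tm {pair.homology_tm_rev:.1f} degC")

amplicon = simulate_pcr(template, pair, template_name="myGene")
print(f"\namplicon: {len(amplicon)} bp "
      f"(= 30 nt site + {len(template)} bp template + 30 nt site)")
print(f"extension time at 1 min/kb: {extension_time(len(amplicon)):.2f} min")
print(f"classifies as: {classify_fragment(amplicon.sequence)}")
# The amplicon's terminal 30-mers are sites #4 and #5, so it drops into the
# gB position of any compatible assembly.
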