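# Methods

This note documents the models behind `gmapkit`, the defaults and their
units, the synthetic-data generator, and the numerical choices made where
the design was genuinely open. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The overlap-site grammar

Five fixed 30-nt sequences (sites #1–#5) act as positional addresses.
A *slot* is an ordered pair of sites with left id < right id; the six
canonical slots are pA (1,2), gA (2,3), pB (3,4), gB (4,5), pC (1,4) and
gC (2,5). A part is `left site + core + right site`; a backbone is a
linear vector whose termini carry two sites. Design enumeration
(`enumerate_fills`) is simple-path enumeration over these six edges from
the backbone's start site to its end site; because every edge increases
the site id, the graph is a DAG and enumeration is exact and total.
Output order is fewest fragments first, then lexicographic by slot label,
so command-line output is stable.

pC is assigned flanks (1,4). This is the only assignment under which the
two-fragment design pC:gB tiles a full 1→5 backbone, and it matches the
F1/R4 primer pairing used to build pC parts; an alternative description
of pC as spanning sites 1–3 is internally inconsistent with that design
and was not adopted.

Internal occurrences of a site 30-mer or a screening-enzyme recognition
inside a part's core are reported as warnings, not errors: real inserts
may legitimately contain them, but they create misassembly and screening
hazards the user should see. Sequences are stored uppercase; lowercase
input is upcased; `U` is rejected (DNA only). All coordinates are
0-based, half-open.

Sites #2, #3 and #4 embed NheI, AvrII and AfeI recognitions (offset 11 in
each 30-mer). No recognition from the shipped panel occurs in sites #1 or
#5, so their `encoded_enzyme` is deliberately left unset rather than
guessed; the panel itself is a user-extensible TSV.

## Primer design and PCR simulation

A part's forward primer is its slot's left 30-mer (5' overhang) followed
by template homology; the reverse primer is the reverse complement of the
right 30-mer followed by reverse-complement homology. Homology is grown
3'-ward one base at a time from `homology_min` (18 nt) until its melting
temperature reaches `tm_target` (62 °C, the protocol's annealing
temperature), clamped at `homology_max` (35 nt); an unreachable target
yields a warning, not an error, since AT-rich templates are real. Growth
is deterministic — no ties are possible.

Tm defaults to nearest-neighbor thermodynamics with the unified parameter
set at 50 mM monovalent salt and 500 nM primer (primer in excess, template
negligible); the protocol specifies only the annealing temperature, so
these are conventional PCR conditions, not measured ones. The Wallace rule
(2·AT + 4·GC) is used below 14 nt, where the NN model is unreliable.
Secondary structure, primer dimers and polymerase-specific corrections are
out of scope.

PCR simulation requires exact, unique homology matches (the platform's
primers are designed against their own templates): zero matches is a
no-amplification error, multiple matches an ambiguity error listing the
0-based positions. By construction,
`simulate_pcr(design_part_primers(T, s), T)` equals the directly flanked
part, and classifies back to slot `s` — a property the suite checks over
200 seeded random templates of 100–2000 bp.

Extension time is `length / 1000 × rate` with the protocol's default rate
1 min/kb.

## Assembly simulation

Overlap detection is exact-match terminal homology: for every ordered pair
of oriented fragments the longest suffix–prefix match of at least
`min_overlap` (default 30 nt, the designed site length; configurable
15–40) becomes a junction-graph edge. There is no mismatch tolerance and
no thermodynamic model of chew-back/annealing kinetics — designed
junctions are exact, and modeling the enzymology would add parameters the
simulation cannot ground.

`assemble` enumerates simple cycles through the backbone over any
sub-multiset of the supplied fragments (one-pot semantics: everything in
the tube competes). Exactly one distinct circle is success; zero raises an
incomplete-assembly error that names the unmatched terminal sites (for
each site id, terminal occurrences as fragment starts and ends must pair
off; unbalanced ids are the gap); more than one — for example a second
competing gB part — raises an ambiguity error carrying all products.
Products are canonicalized by rotating to the backbone's first base with
the backbone forward; for backbone-less enumeration the canonical form is
the lexicographically least rotation of the lesser strand (Booth's
algorithm), which also powers deduplication up to rotation and reverse
complement. Total length always equals Σ fragment lengths − Σ overlap
lengths; the suite property-tests this and the invariance of the canonical
product under fragment shuffling and strand flipping. Terminal 30-mers
that also occur internally are surfaced as misassembly warnings but do not
influence cycle finding. Only circular products are modeled; the
platform's backbones circularize, and linear assembly is out of scope.

## Digestion and screening

Recognition search expands IUPAC codes and scans both strands, reporting
palindromic duplex sites once; on circular substrates the search wraps the
origin. Cut bookkeeping reduces both strands to the top-strand cut
coordinate, and fragment lengths are duplex lengths: screening reads band
sizes off an agarose gel, so sticky-end identity is not tracked. Fragment
lengths always sum to substrate length. The implementation is
cross-checked in the tests against an independent rotate-and-scan oracle
and against a reference digestion library on linear substrates.

Screening-plan scoring: for each enzyme, digest the intended product and
each alternative, pool the band lengths, merge neighbours whose fractional
difference is below the gel-resolution tolerance (default 0.10, typical
agarose discrimination) into size classes, and sum per-class count
differences weighted by log10 of the class's representative length. The
score per enzyme is the worst case (minimum) over alternatives; 0 means
some alternative is invisible to that enzyme. A known limitation follows
from the sizes-only model: a single-cut product and an uncut circle of
similar total size are scored indistinguishable, although on a real gel
supercoiled and linear molecules migrate differently.

Sequencing verification uses a configurable primer panel (default: the
five site 30-mers themselves, which anneal to every junction the grammar
can form) and asserts each junction lies within one read length (default
700 nt, configurable; no standard value is fixed by the protocol) of a
primer footprint, allowing a configurable mismatch budget.

## Reaction math

dsDNA molar mass uses the anhydrous salt-free convention 617.96 g/mol per
bp + 36.04 g/mol for the ends. The standard layout: each insert
contributes 5.7 × 10⁻² pmol (1 µL of the 57 nM normalized stock), pooled
inserts are topped up to 5 µL with TE, 15 µL master mix is added, and the
reaction runs at 50 °C for 20 min; the backbone enters at 200 ng with its
molar amount derived from length. The phrase "5 µL of inserts at
5.7 × 10⁻² pmol each" is interpreted as per-insert amounts within a fixed
5 µL pooled volume (the plan warns when the pool overflows); the
alternative reading (5 µL per insert) would make the stated total reaction
volume impossible for multi-insert reactions.

`colonies_to_screen(p, c)` returns the smallest n with 1 − (1−p)ⁿ
strictly greater than c, computed in closed form with a floating-point
guard around the boundary; "greater than" is treated as strict, so an n
that hits the confidence exactly is incremented. The suite verifies the
closed form against a brute-force loop over 10⁴ sampled (p, c) pairs.
Per-colony efficiencies are construct-dependent and not fixed by the
platform, so the efficiency table ships empty; the familiar three-colony
(two-fragment) and five-colony (four-fragment) guidance is reproduced
under assumed efficiencies of 0.80 and 0.65, and
`ILLUSTRATIVE_EFFICIENCIES` is explicitly labeled as non-measured.

## Synthetic fixtures

Real part collections and retrofitted vectors are distributed as physical
plasmids, so the generator replicates their architectures, not their
sequences; everything derives from a single integer seed
(identical spec → byte-identical output). Part cores are random DNA at a
target GC (default 0.5), lengths uniform in a configurable range (default
300–1500 bp, spanning typical promoters and ORFs), rejection-sampled
(capped at 10⁵ attempts, then a loud failure) to exclude the five site
30-mers and the panel recognitions so that fixture parts are warning-free
and screening counts are predictable.

Backbone plasmids read `[start site][spacer][end site][vector]` around a
circle (default vector stuffer 2.5 kb at GC 0.5). Spacer termini are
engineered so the declared releasing enzymes cut flush at the site
boundaries. The geometry falls out of the site sequences themselves:
PmeI's blunt GTTT^AAAC straddles any boundary where the upstream side ends
GTTT (sites #1 and #2 do) and the downstream side begins AAAC (sites #3
and #5 do); BsrGI's T^GTACA is flush after any site ending in T when the
spacer begins GTACA. For a 1–5 backbone released by PmeI+BsrGI the
generator assigns BsrGI to the site1|spacer boundary and PmeI to
spacer|site5 so both declared enzymes cut, both flush. One boundary class
has no flush solution over the shipped panel — a spacer|site4 boundary,
because site #4 begins GACCC, which no panel recognition's post-cut tail
matches (checked exhaustively over the panel's cut geometries). There the
generator embeds the recognition at the spacer edge: the released fragment
still measures exactly the declared spacer length (lengths are defined
cut-to-cut), but a short recognition remnant (5 nt for NheI) remains on
that backbone terminus. This affects the 1–4 architecture only; 1–5 and
2–5 backbones have both sites perfectly terminal, and those are the
architectures the assembly tests use. The generator finally digests the
whole plasmid and rejects any sample that does not produce exactly the two
intended cuts.

What fixtures do not emulate: real promoter/gene sequence composition
(GC skew, repeats, homopolymers), vector replication elements, methylation,
and any biological function. Passing tests therefore demonstrate the
correctness of the grammar, design, assembly and screening *logic* on
sequences with the platform's architecture — not performance on any
particular biological insert.

## Problem sizes and determinism

The test suite runs fixture parts with 120–600 bp cores and products of a
few kb, 200-template PCR round-trips, rotate-and-scan digestion oracles on
3–5 kb circles, and a 10⁴-point colony-statistics grid — sizes chosen so
the whole suite completes in seconds while exercising every invariant at
realistic molecule scales. All randomness is seeded (`random.Random` /
Hypothesis with fixed examples), and the CLI's `--seed` flag flows into
every generator, so outputs are reproducible byte for byte.
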