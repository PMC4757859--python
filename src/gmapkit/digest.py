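"""Restriction-digest simulation and clone screening.

The platform's overlap sites #2, #3 and #4 each embed a unique screening
enzyme recognition (NheI, AvrII, AfeI), so a correct multi-part assembly
shows a predictable band pattern.  This module predicts those patterns:
IUPAC recognition-site search on circular or linear duplexes,
fragment-size computation, ranking of discriminating enzymes against
candidate misassemblies, and sequencing-primer annealing-site checks.

Cut bookkeeping uses the top-strand cut coordinate only and duplex fragment
lengths — screening reads band sizes off a gel, not end chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import EnzymeError, GmapError, SequenceError
from .sequences import clean_sequence, revcomp

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: The screening panel named in the platform's protocol, plus the two
#: backbone-release enzymes.
DEFAULT_PANEL_NAMES = ("XmaI", "NheI", "AvrII", "AfeI", "AscI", "PmeI", "BsrGI")

SCREENING_ENZYMES = ("XmaI", "NheI", "AvrII", "AfeI", "AscI")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction endonuclease: IUPAC recognition and cut offsets.

    ``cut_top`` / ``cut_bottom`` are offsets from the recognition's 5' end
    on the strand it reads from; blunt cutters have ``cut_top == cut_bottom``.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self):
        rec = self.recognition.upper()
        for i, ch in enumerate(rec):
            if ch not in IUPAC_CODES:
                raise EnzymeError(
                    f"enzyme {self.name}: invalid IUPAC code {ch!r} at "
                    f"position {i} of recognition {self.recognition!r}"
                )
        object.__setattr__(self, "recognition", rec)

    @property
    def is_palindromic(self) -> bool:
        rc = self.recognition.translate(_IUPAC_COMPLEMENT)[::-1]
        return rc == self.recognition

    def rc_recognition(self) -> str:
        return self.recognition.translate(_IUPAC_COMPLEMENT)[::-1]


def load_enzyme_panel(path: str | Path | None = None) -> dict[str, EnzymeSpec]:
    """Load the packaged enzyme table (or a user TSV of the same layout)."""
    if path is None:
        text = (resources.files("gmapkit") / "data" / "enzymes.tsv").read_text()
    else:
        text = Path(path).read_text()
    panel: dict[str, EnzymeSpec] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:  # skip header
        name, rec, ct, cb = ln.split("\t")
        panel[name] = EnzymeSpec(name, rec, int(ct), int(cb))
    return panel


def _iupac_match(seq: str, pattern: str, at: int) -> bool:
    for j, code in enumerate(pattern):
        if seq[at + j] not in IUPAC_CODES[code]:
            return False
    return True


def find_recognition_sites(
    seq: str, enzyme: EnzymeSpec, circular: bool = False
) -> list[tuple[int, str]]:
    """0-based start positions of recognition matches on both strands.

    Returns (position, strand) tuples with strand '+' or '-'; positions are
    on the top strand and refer to the leftmost base of the duplex site.
    Palindromic recognitions are reported once per duplex site.  When
    ``circular``, matches spanning the origin are included and positions
    are reported modulo the length.
    """
    seq = clean_sequence(seq, what="substrate")
    L, rlen = len(seq), len(enzyme.recognition)
    if rlen > L:
        return []
    search = seq + seq[: rlen - 1] if circular else seq
    hits: list[tuple[int, str]] = []
    patterns = [(enzyme.recognition, "+")]
    if not enzyme.is_palindromic:
        patterns.append((enzyme.rc_recognition(), "-"))
    for pattern, strand in patterns:
        for p in range(len(search) - rlen + 1):
            if _iupac_match(search, pattern, p):
                hits.append((p % L, strand))
    hits = sorted(set(hits))
    return hits


@dataclass
class DigestResult:
    """Cut coordinates and the multiset of fragment sizes they imply."""

    cut_positions: list[int]
    fragment_lengths: list[int]
    is_circular: bool
    substrate_length: int
    enzymes: list[str] = field(default_factory=list)


def _cut_coordinates(seq_len: int, seq: str, enzyme: EnzymeSpec, circular: bool) -> set[int]:
    rlen = len(enzyme.recognition)
    cuts: set[int] = set()
    for pos, strand in find_recognition_sites(seq, enzyme, circular=circular):
        if strand == "+":
            c = pos + enzyme.cut_top
        else:
            # recognition reads on the bottom strand; its bottom-strand cut
            # is the duplex top-strand cut here
            c = pos + rlen - enzyme.cut_bottom
        if circular:
            cuts.add(c % seq_len)
        elif 0 <= c <= seq_len:
            cuts.add(c)
    return cuts


def digest(
    seq: str, enzymes: list[EnzymeSpec] | EnzymeSpec, circular: bool = False
) -> DigestResult:
    """Fragment sizes from digesting a substrate with one or more enzymes.

    Zero cuts is a valid result: a circular substrate then yields a single
    fragment of its own length (the uncut circle).  Fragment lengths always
    sum to the substrate length.
    """
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    seq = clean_sequence(seq, what="substrate")
    L = len(seq)
    cuts: set[int] = set()
    for enz in enzymes:
        cuts |= _cut_coordinates(L, seq, enz, circular)
    sorted_cuts = sorted(cuts)
    if circular:
        if not sorted_cuts:
            fragments = [L]
        else:
            fragments = [
                (sorted_cuts[(i + 1) % len(sorted_cuts)] - c) % L or L
                for i, c in enumerate(sorted_cuts)
            ]
            # a single cut linearizes: one fragment of full length
    else:
        bounds = [0] + sorted_cuts + [L]
        fragments = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
        if not fragments:
            fragments = [L]
    return DigestResult(
        cut_positions=sorted_cuts,
        fragment_lengths=sorted(fragments),
        is_circular=circular,
        substrate_length=L,
        enzymes=[e.name for e in enzymes],
    )


# ---------------------------------------------------------------------------
# screening-plan scoring


def _merge_classes(lengths: list[int], tolerance: float) -> list[list[int]]:
    """Greedy chain-merge of sorted lengths: neighbours whose fractional
    difference is below tolerance fall in one gel size class."""
    classes: list[list[int]] = []
    for x in sorted(lengths):
        if classes and (x - classes[-1][-1]) / max(x, 1) < tolerance:
            classes[-1].append(x)
        else:
            classes.append([x])
    return classes


def band_pattern_distance(a: list[int], b: list[int], tolerance: float = 0.10) -> float:
    """Distance between two digest band patterns at a gel resolution.

    Lengths from both patterns are pooled and merged into size classes
    (fractional difference < tolerance is indistinguishable on a gel); the
    distance is the per-class count difference weighted by log10 of the
    class's representative length.  0 iff the patterns are indistinguishable.
    """
    classes = _merge_classes(list(a) + list(b), tolerance)
    from collections import Counter

    ca, cb = Counter(a), Counter(b)
    dist = 0.0
    for cls in classes:
        na = sum(ca[x] for x in set(cls))
        nb = sum(cb[x] for x in set(cls))
        rep = math.exp(sum(math.log(x) for x in cls) / len(cls))
        dist += abs(na - nb) * math.log10(max(rep, 2.0))
    return dist


@dataclass
class ScreeningPlan:
    """Enzymes ranked by how well they separate correct from wrong clones."""

    ranked: list[tuple[str, float]]  # (enzyme name, discrimination score)
    resolution_tolerance: float

    @property
    def best(self) -> str:
        return self.ranked[0][0]


def _product_sequence(product) -> str:
    return product if isinstance(product, str) else product.sequence


def discriminating_enzymes(
    correct,
    alternatives: list,
    panel: list[EnzymeSpec],
    tolerance: float = 0.10,
) -> ScreeningPlan:
    """Rank panel enzymes by worst-case band-pattern distance between the
    intended circular product and each alternative assembly.

    Score per enzyme is the minimum distance over alternatives, so a score
    of 0 means some misassembly is invisible to that enzyme at the stated
    gel resolution.  Ties are broken alphabetically.
    """
    if not panel:
        raise GmapError("empty enzyme panel")
    if not alternatives:
        raise GmapError("need at least one alternative product to screen against")
    correct_seq = _product_sequence(correct)
    scores: list[tuple[str, float]] = []
    for enz in panel:
        ref = digest(correct_seq, enz, circular=True).fragment_lengths
        score = min(
            band_pattern_distance(
                ref,
                digest(_product_sequence(alt), enz, circular=True).fragment_lengths,
                tolerance,
            )
            for alt in alternatives
        )
        scores.append((enz.name, score))
    scores.sort(key=lambda t: (-t[1], t[0]))
    return ScreeningPlan(ranked=scores, resolution_tolerance=tolerance)


# ---------------------------------------------------------------------------
# sequencing-primer checks


def primer_annealing_sites(
    seq: str,
    primer: str,
    circular: bool = False,
    max_mismatch: int = 0,
) -> list[tuple[int, str]]:
    """Positions (both strands) where a primer anneals with at most
    ``max_mismatch`` substitutions.

    Positions are top-strand 0-based starts of the primer's footprint;
    strand '+' means the primer reads along the top strand (extends
    rightward), '-' along the bottom (extends leftward).  Origin-spanning
    footprints on circular substrates are detected.
    """
    primer = clean_sequence(primer, what="primer")
    if len(primer) < 15:
        raise SequenceError(
            f"sequencing primer must be >= 15 nt, got {len(primer)}"
        )
    seq = clean_sequence(seq, what="substrate")
    L, plen = len(seq), len(primer)
    if plen > L:
        return []
    search = seq + seq[: plen - 1] if circular else seq
    hits: list[tuple[int, str]] = []
    rc_primer = revcomp(primer)
    for query, strand in ((primer, "+"), (rc_primer, "-")):
        for p in range(len(search) - plen + 1):
            mism = sum(1 for a, b in zip(search[p : p + plen], query) if a != b)
            if mism <= max_mismatch:
                hits.append((p % L, strand))
    return sorted(set(hits))


def junction_coverage(
    product,
    primers: dict[str, str] | None = None,
    read_length: int = 700,
    max_mismatch: int = 0,
) -> dict[int, str | None]:
    """For each junction of an assembly product, the name of a panel primer
    whose annealing site lies within ``read_length`` nt upstream (so a
    Sanger read from it crosses the junction); ``None`` if uncovered.

    The default primer panel is the five overlap-site 30-mers themselves —
    they anneal to every junction the grammar can produce.
    """
    from .registry import SITE_SEQUENCES

    if primers is None:
        primers = {f"site{j}_seq": s for j, s in SITE_SEQUENCES.items()}
    seq = _product_sequence(product)
    L = len(seq)
    sites: list[tuple[int, str, str]] = []
    for name, p in primers.items():
        for pos, strand in primer_annealing_sites(
            seq, p, circular=True, max_mismatch=max_mismatch
        ):
            sites.append((pos, strand, name))
    coverage: dict[int, str | None] = {}
    for junc in product.junctions:
        jpos = junc.position_in_product
        covering = None
        for pos, strand, name in sites:
            if strand == "+":
                dist = (jpos - pos) % L
            else:
                dist = (pos - jpos) % L
            if 0 <= dist <= read_length:
                covering = name
                break
        coverage[jpos] = covering
    return coverage
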