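"""Part registry: the five overlap sites and the slot grammar.

The platform positions every fragment in a construct with five fixed 30-nt
"overlap sites".  A *slot* names a (left site, right site) pair: promoters
occupy pA (1,2), pB (3,4) or pC (1,4); genes occupy gA (2,3), gB (4,5) or
gC (2,5).  A *part* is a core sequence flanked by its slot's two sites; a
*backbone* is a linearized vector whose termini carry two sites, so that a
set of parts whose sites tile consecutively between the backbone's termini
closes into a circle under Gibson assembly.

Sites #2, #3 and #4 each embed a unique screening enzyme's recognition
(NheI, AvrII, AfeI at offset 11); no packaged enzyme recognition occurs in
sites #1 or #5, so their ``encoded_enzyme`` is left unset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SequenceError, SlotError
from .sequences import clean_sequence

SITE_LENGTH = 30

#: The five canonical 30-nt overlap sites, by id.
SITE_SEQUENCES: dict[int, str] = {
    1: "GATCAGTGTGAGGGAGTGTAAAGCTGGTTT",
    2: "CTAACTCGAACGCTAGCTGTGCGATCGTTT",
    3: "AAACCGCTGTTCCTAGGAATCCCGAGGCCT",
    4: "GACCCGACATTAGCGCTACAGCTTAAGCGG",
    5: "AAACGTTGTTGTTTGGGGTTGAATTACTCT",
}

#: Screening enzyme whose recognition is embedded in each site (where one is).
SITE_ENCODED_ENZYMES: dict[int, str | None] = {
    1: None,
    2: "NheI",
    3: "AvrII",
    4: "AfeI",
    5: None,
}


@dataclass(frozen=True)
class OverlapSite:
    """One of the five canonical junction sequences."""

    id: int
    sequence: str
    encoded_enzyme: str | None = None

    def __post_init__(self):
        if not 1 <= self.id <= 5:
            raise SlotError(f"site id must be in 1..5, got {self.id}")
        if len(self.sequence) != SITE_LENGTH:
            raise SequenceError(
                f"overlap site #{self.id} must be {SITE_LENGTH} nt, "
                f"got {len(self.sequence)}"
            )
        clean_sequence(self.sequence, what=f"site #{self.id}")


SITES: dict[int, OverlapSite] = {
    i: OverlapSite(i, SITE_SEQUENCES[i], SITE_ENCODED_ENZYMES[i]) for i in range(1, 6)
}

#: Slot grammar: slot label -> (left site id, right site id).
SLOT_EDGES: dict[str, tuple[int, int]] = {
    "pA": (1, 2),
    "gA": (2, 3),
    "pB": (3, 4),
    "gB": (4, 5),
    "pC": (1, 4),
    "gC": (2, 5),
}

PROMOTER_SLOTS = ("pA", "pB", "pC")
GENE_SLOTS = ("gA", "gB", "gC")


def slot_role(slot: str) -> str:
    """'promoter' or 'gene' for a canonical slot label."""
    if slot in PROMOTER_SLOTS:
        return "promoter"
    if slot in GENE_SLOTS:
        return "gene"
    raise SlotError(f"unknown slot label {slot!r}")


def flanks_for_slot(slot: str) -> tuple[OverlapSite, OverlapSite]:
    """The (left, right) overlap sites flanking a slot.

    >>> flanks_for_slot("pA")[0].id, flanks_for_slot("pA")[1].id
    (1, 2)
    """
    try:
        left, right = SLOT_EDGES[slot]
    except KeyError:
        raise SlotError(
            f"unknown slot label {slot!r}; expected one of "
            f"{', '.join(SLOT_EDGES)}"
        ) from None
    return SITES[left], SITES[right]


@dataclass
class Part:
    """A promoter or gene core flanked by its slot's overlap sites."""

    name: str
    role: str
    slot: str
    core_sequence: str
    flanked_sequence: str
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.flanked_sequence)


@dataclass
class Backbone:
    """A linearized destination vector with overlap sites at its termini.

    ``sequence`` is the top strand 5'->3'; one terminus equals the
    chain-start site's 30-mer and the other the chain-end site's (in either
    order on the stored strand — assembly handles orientation).
    """

    name: str
    sequence: str
    chain_start_site: int
    chain_end_site: int
    source_note: str = ""

    def __post_init__(self):
        if not (1 <= self.chain_start_site < self.chain_end_site <= 5):
            raise SlotError(
                "backbone chain sites must satisfy 1 <= start < end <= 5, got "
                f"({self.chain_start_site}, {self.chain_end_site})"
            )
        self.sequence = clean_sequence(
            self.sequence, what=f"backbone {self.name}", min_length=2 * SITE_LENGTH
        )

    def __len__(self) -> int:
        return len(self.sequence)


def _internal_warnings(core: str) -> list[str]:
    """Warnings for overlap-site 30-mers or screening recognitions inside a core."""
    # local import: digest depends on registry for site constants
    from .digest import DEFAULT_PANEL_NAMES, find_recognition_sites, load_enzyme_panel

    warnings = []
    for sid, site in SITE_SEQUENCES.items():
        pos = core.find(site)
        if pos != -1:
            warnings.append(
                f"core contains overlap site #{sid} 30-mer at position {pos}"
            )
    panel = load_enzyme_panel()
    for enz_name in DEFAULT_PANEL_NAMES:
        hits = find_recognition_sites(core, panel[enz_name], circular=False)
        if hits:
            warnings.append(
                f"core contains {enz_name} recognition at position(s) "
                f"{', '.join(str(p) for p, _ in hits)}"
            )
    return warnings


def make_flanked_part(core: str, slot: str, name: str = "") -> Part:
    """Flank a core sequence with its slot's sites, producing a Part.

    Internal occurrences of any canonical 30-mer or screening-panel
    recognition are reported as warnings, not errors — real inserts may
    legitimately contain them, but they can confound screening or assembly.
    """
    core = clean_sequence(core, what="core sequence")
    left, right = flanks_for_slot(slot)
    flanked = left.sequence + core + right.sequence
    return Part(
        name=name or f"{slot}_part",
        role=slot_role(slot),
        slot=slot,
        core_sequence=core,
        flanked_sequence=flanked,
        warnings=_internal_warnings(core),
    )


def classify_fragment(seq: str) -> str | None:
    """The unique slot whose sites are the first and last 30-mers of seq.

    Returns ``None`` when no slot matches; rejects sequences shorter than
    two site lengths (60 nt).
    """
    seq = clean_sequence(seq, what="fragment", min_length=2 * SITE_LENGTH)
    head, tail = seq[:SITE_LENGTH], seq[-SITE_LENGTH:]
    ids = {s: i for i, s in SITE_SEQUENCES.items()}
    left, right = ids.get(head), ids.get(tail)
    if left is None or right is None:
        return None
    for slot, (l, r) in SLOT_EDGES.items():
        if (l, r) == (left, right):
            return slot
    return None


def enumerate_fills(backbone: Backbone) -> list[list[str]]:
    """Every slot sequence whose sites tile the backbone's chain.

    Enumerates simple paths over the grammar's edges from
    ``chain_start_site`` to ``chain_end_site``; ordered fewest-fragments
    first, then lexicographically by slot labels.  For the canonical (1,5)
    backbone this yields the platform's three designs:
    ``[pA,gA,pB,gB]``, ``[pA,gC]`` and ``[pC,gB]``.
    """
    start, end = backbone.chain_start_site, backbone.chain_end_site
    out: list[list[str]] = []

    def walk(at: int, path: list[str]) -> None:
        if at == end:
            out.append(list(path))
            return
        for slot, (l, r) in SLOT_EDGES.items():
            if l == at and r <= end:
                path.append(slot)
                walk(r, path)
                path.pop()

    walk(start, [])
    out.sort(key=lambda p: (len(p), p))
    return out


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    part: str
    checks: list[ValidationCheck]
    warnings: list[str]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]


def validate_part(part: Part) -> ValidationReport:
    """Check a Part's flank identity and site lengths; never raises."""
    checks: list[ValidationCheck] = []
    try:
        left, right = flanks_for_slot(part.slot)
    except SlotError as exc:
        return ValidationReport(
            part.name, [ValidationCheck("slot-known", False, str(exc))], []
        )
    checks.append(
        ValidationCheck(
            "site-length-30",
            len(left.sequence) == SITE_LENGTH and len(right.sequence) == SITE_LENGTH,
        )
    )
    flank_ok = (
        part.flanked_sequence.startswith(left.sequence)
        and part.flanked_sequence.endswith(right.sequence)
        and part.flanked_sequence
        == left.sequence + part.core_sequence + right.sequence
    )
    checks.append(
        ValidationCheck(
            "flank-identity",
            flank_ok,
            "" if flank_ok else (
                f"flanked sequence does not equal site#{left.id} + core + "
                f"site#{right.id} for slot {part.slot}"
            ),
        )
    )
    checks.append(
        ValidationCheck("core-nonempty", len(part.core_sequence) >= 1)
    )
    warnings = _internal_warnings(part.core_sequence) if flank_ok else list(part.warnings)
    return ValidationReport(part.name, checks, warnings)
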