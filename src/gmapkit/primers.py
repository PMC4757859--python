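"""Slot-specific primer design and PCR simulation.

A part enters the platform by PCR: the forward primer carries the slot's
left overlap site as a 5' overhang ahead of template homology, the reverse
primer carries the reverse complement of the right site.  The F/R naming
follows the site ids — F4 + R5 produce a gB part, F1 + R2 a pA part, and
so on.  Amplification conditions mirror the protocol the collections were
built with: 62 degC annealing and 1 min/kb extension.

Homology length is grown 3'-ward one base at a time from ``homology_min``
until the homology melting temperature reaches ``tm_target`` (clamped at
``homology_max``); Tm estimation uses nearest-neighbor thermodynamics with
the unified parameter set at 50 mM monovalent salt and 500 nM primer, with
the Wallace rule as an explicit fallback for very short oligos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .errors import (
    AmbiguousAmplificationError,
    AmplificationError,
    GmapError,
    PrimerDesignError,
    SequenceError,
)
from .registry import SITE_LENGTH, flanks_for_slot
from .sequences import clean_sequence, revcomp

#: Conditions assumed by the nearest-neighbor model (the protocol states
#: only the annealing temperature, not a Tm model).
NN_MONOVALENT_MM = 50.0   # mM Na+
NN_PRIMER_NM = 500.0      # nM primer, template negligible

WALLACE_MAX_RELIABLE = 13  # NN preferred at >= 14 nt


@dataclass
class PrimerParams:
    """Tunables for primer design and the PCR program."""

    tm_target: float = 62.0       # degC, homology melting target = annealing temp
    homology_min: int = 18        # nt
    homology_max: int = 35        # nt
    tm_method: str = "nearest-neighbor"
    extension_rate: float = 1.0   # min per kb
    annealing_temp: float = 62.0  # degC

    def __post_init__(self):
        if self.homology_min > self.homology_max:
            raise GmapError(
                f"homology_min {self.homology_min} > homology_max {self.homology_max}"
            )
        if self.extension_rate <= 0:
            raise GmapError("extension_rate must be positive")
        if self.tm_method not in ("nearest-neighbor", "wallace"):
            raise GmapError(f"unknown Tm method {self.tm_method!r}")


def melting_temperature(seq: str, method: str = "nearest-neighbor") -> float:
    """Duplex melting temperature of an oligo, degC.

    ``wallace``: the rule-of-thumb 2*(A+T) + 4*(G+C), valid for short
    oligos (>= 2 nt).  ``nearest-neighbor``: unified-parameter NN estimate
    (SantaLucia) at 50 mM monovalent salt, 500 nM primer; requires >= 8 nt.
    """
    seq = clean_sequence(seq, what="oligo")
    if method == "wallace":
        if len(seq) < 2:
            raise SequenceError("Wallace rule needs >= 2 nt")
        return float(_mt.Tm_Wallace(seq))
    if method == "nearest-neighbor":
        if len(seq) < 8:
            raise SequenceError("nearest-neighbor Tm needs >= 8 nt")
        return float(
            _mt.Tm_NN(
                seq,
                nn_table=_mt.DNA_NN3,
                Na=NN_MONOVALENT_MM,
                K=0, Tris=0, Mg=0, dNTPs=0,
                dnac1=NN_PRIMER_NM,
                dnac2=0,
                saltcorr=5,
            )
        )
    raise GmapError(f"unknown Tm method {method!r}")


def _auto_tm(seq: str, params: PrimerParams) -> float:
    """Configured Tm method, falling back to Wallace below the NN range."""
    if params.tm_method == "wallace" or len(seq) <= WALLACE_MAX_RELIABLE:
        return melting_temperature(seq, "wallace")
    return melting_temperature(seq, "nearest-neighbor")


@dataclass
class PrimerPair:
    """An overhang-bearing F/R primer pair for one slot."""

    forward: str
    reverse: str
    overhang_len_fwd: int
    overhang_len_rev: int
    homology_tm_fwd: float
    homology_tm_rev: float
    slot: str
    forward_name: str = ""
    reverse_name: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def forward_homology(self) -> str:
        return self.forward[self.overhang_len_fwd :]

    @property
    def reverse_homology(self) -> str:
        return self.reverse[self.overhang_len_rev :]


@dataclass
class Amplicon:
    sequence: str
    template_name: str
    primer_pair: PrimerPair

    def __len__(self) -> int:
        return len(self.sequence)


def _grow_homology(region: str, params: PrimerParams) -> tuple[str, float, bool]:
    """Shortest prefix of ``region`` with Tm >= target, clamped to
    [homology_min, homology_max].  Returns (homology, tm, reached_target)."""
    n = params.homology_min
    h = region[:n]
    tm = _auto_tm(h, params)
    while tm < params.tm_target and n < min(params.homology_max, len(region)):
        n += 1
        h = region[:n]
        tm = _auto_tm(h, params)
    return h, tm, tm >= params.tm_target


def design_part_primers(
    template: str, slot: str, params: PrimerParams | None = None, name: str = ""
) -> PrimerPair:
    """Design the slot's F/R pair against a full-length template core.

    The forward primer is the slot's left 30-mer followed by the shortest
    template prefix reaching the Tm target; the reverse primer is the
    reverse complement of the right 30-mer followed by the reverse
    complement of the shortest template suffix reaching the target.  If the
    target is unreachable within ``homology_max`` the pair is returned with
    a below-target warning rather than an error.
    """
    params = params or PrimerParams()
    template = clean_sequence(template, what="template")
    if len(template) < 2 * params.homology_min:
        raise PrimerDesignError(
            f"template of {len(template)} nt cannot host two homologies of "
            f">= {params.homology_min} nt"
        )
    left, right = flanks_for_slot(slot)
    fwd_hom, fwd_tm, fwd_ok = _grow_homology(template, params)
    rev_region = revcomp(template)  # suffix of template, read 5'->3' on bottom strand
    rev_hom, rev_tm, rev_ok = _grow_homology(rev_region, params)
    warnings = []
    if not fwd_ok:
        warnings.append(
            f"forward homology Tm {fwd_tm:.1f} degC below target {params.tm_target} degC"
        )
    if not rev_ok:
        warnings.append(
            f"reverse homology Tm {rev_tm:.1f} degC below target {params.tm_target} degC"
        )
    return PrimerPair(
        forward=left.sequence + fwd_hom,
        reverse=revcomp(right.sequence) + rev_hom,
        overhang_len_fwd=SITE_LENGTH,
        overhang_len_rev=SITE_LENGTH,
        homology_tm_fwd=fwd_tm,
        homology_tm_rev=rev_tm,
        slot=slot,
        forward_name=f"{name or slot}_F{left.id}",
        reverse_name=f"{name or slot}_R{right.id}",
        warnings=warnings,
    )


def _find_once(template: str, query: str, what: str) -> int:
    positions = []
    at = template.find(query)
    while at != -1:
        positions.append(at)
        at = template.find(query, at + 1)
    if not positions:
        raise AmplificationError(f"{what} has no binding site in the template")
    if len(positions) > 1:
        raise AmbiguousAmplificationError(
            f"{what} binds the template at {len(positions)} positions: "
            f"{positions}", positions
        )
    return positions[0]


def simulate_pcr(template: str, pair: PrimerPair, template_name: str = "") -> Amplicon:
    """Amplicon from a primer pair on a template (exact homology, zero
    mismatches — the platform's primers are designed against their own
    templates).

    Errors when either homology is absent (no amplification) or present
    more than once (ambiguous product)."""
    template = clean_sequence(template, what="template")
    f_start = _find_once(template, pair.forward_homology, "forward primer homology")
    rev_on_top = revcomp(pair.reverse_homology)
    r_at = _find_once(template, rev_on_top, "reverse primer homology")
    r_end = r_at + len(rev_on_top)
    if r_end <= f_start:
        raise AmplificationError(
            "primer binding sites are not in amplifiable orientation "
            f"(forward at {f_start}, reverse homology ends at {r_end})"
        )
    overhang_fwd = pair.forward[: pair.overhang_len_fwd]
    overhang_rev = pair.reverse[: pair.overhang_len_rev]
    sequence = overhang_fwd + template[f_start:r_end] + revcomp(overhang_rev)
    return Amplicon(sequence=sequence, template_name=template_name, primer_pair=pair)


def extension_time(amplicon_length: int, params: PrimerParams | None = None) -> float:
    """PCR extension time in minutes at the protocol's 1 min/kb rate."""
    params = params or PrimerParams()
    if amplicon_length < 1:
        raise GmapError(f"amplicon length must be >= 1 bp, got {amplicon_length}")
    return amplicon_length / 1000.0 * params.extension_rate
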