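"""Seeded synthetic part and backbone generators.

The platform's real promoter/gene collections and retrofitted vectors are
distributed physically, not printed, so tests and examples run on
synthetic stand-ins that replicate the published *architectures*: parts
are random cores flanked by their slot's overlap sites; backbone plasmids
are circular molecules carrying ``[chain-start site][spacer][chain-end
site]`` in a random vector, with the spacer termini engineered so the
declared releasing enzymes cut flush at the site boundaries (a PmeI
recognition, GTTTAAAC, straddles any boundary where one side ends GTTT
and the other begins AAAC — which is exactly how sites #1/#2 end and
sites #3/#5 begin).  Digesting the plasmid releases the spacer as one
fragment of the declared length and leaves the linearized backbone with
the two overlap sites at its termini.

Everything is deterministic under the spec's seed: identical
``FixtureSpec`` -> byte-identical sequences.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .digest import EnzymeSpec, digest, load_enzyme_panel
from .errors import FixtureError, GmapError
from .registry import (
    GENE_SLOTS,
    PROMOTER_SLOTS,
    SITE_SEQUENCES,
    Backbone,
    Part,
    make_flanked_part,
)

MAX_SAMPLING_ATTEMPTS = 100_000


@dataclass(frozen=True)
class BackboneArch:
    """Architecture of a backbone plasmid: chain sites, spacer, releasers."""

    chain_start_site: int = 1
    chain_end_site: int = 5
    spacer_length: int = 469
    enzymes: tuple[str, ...] = ("PmeI", "BsrGI")


@dataclass
class FixtureSpec:
    """Parameters for one deterministic synthetic fixture set."""

    seed: int = 0
    n_promoters: int = 3
    n_genes: int = 3
    core_length_range: tuple[int, int] = (300, 1500)
    gc_fraction: float = 0.5
    backbone_arch: BackboneArch = field(default_factory=BackboneArch)
    forbid_internal: tuple[str, ...] | None = None  # None -> sites + panel
    vector_length: int = 2500

    def forbidden(self) -> tuple[str, ...]:
        if self.forbid_internal is not None:
            return self.forbid_internal
        panel = load_enzyme_panel()
        return tuple(SITE_SEQUENCES.values()) + tuple(
            e.recognition for e in panel.values()
        )


def _random_dna(rng: random.Random, length: int, gc: float) -> str:
    bases = []
    for _ in range(length):
        if rng.random() < gc:
            bases.append("G" if rng.random() < 0.5 else "C")
        else:
            bases.append("A" if rng.random() < 0.5 else "T")
    return "".join(bases)


def _sample_clean(
    rng: random.Random,
    length: int,
    gc: float,
    forbidden: tuple[str, ...],
    prefix: str = "",
    suffix: str = "",
) -> str:
    """Rejection-sample prefix + random + suffix free of forbidden substrings
    (engineered prefix/suffix content excepted only if they are clean too)."""
    fill_len = length - len(prefix) - len(suffix)
    if fill_len < 0:
        raise FixtureError(
            f"length {length} cannot host engineered termini of "
            f"{len(prefix)} + {len(suffix)} nt"
        )
    if any(len(f) < 1 for f in forbidden):
        raise FixtureError("forbidden substrings must be non-empty")
    for _ in range(MAX_SAMPLING_ATTEMPTS):
        s = prefix + _random_dna(rng, fill_len, gc) + suffix
        if not any(f in s for f in forbidden):
            return s
    raise FixtureError(
        f"could not sample a {length} nt sequence avoiding "
        f"{len(forbidden)} forbidden substrings in {MAX_SAMPLING_ATTEMPTS} attempts"
    )


def generate_fixture_parts(spec: FixtureSpec) -> list[Part]:
    """Synthetic promoter and gene parts, slots assigned round-robin
    (promoters pA, pB, pC, ...; genes gA, gB, gC, ...)."""
    rng = random.Random(spec.seed)
    forbidden = spec.forbidden()
    lo, hi = spec.core_length_range
    if lo < 1 or hi < lo:
        raise GmapError(f"bad core_length_range {spec.core_length_range}")
    parts: list[Part] = []
    jobs = [("promoter", PROMOTER_SLOTS, spec.n_promoters), ("gene", GENE_SLOTS, spec.n_genes)]
    for role, slots, count in jobs:
        for i in range(count):
            slot = slots[i % len(slots)]
            core = _sample_clean(rng, rng.randint(lo, hi), spec.gc_fraction, forbidden)
            parts.append(make_flanked_part(core, slot, name=f"{role}_{slot}_{i + 1}"))
    return parts


# ---------------------------------------------------------------------------
# backbone plasmids


def _flush_left(site_seq: str, enz: EnzymeSpec) -> str | None:
    """Spacer prefix making ``enz`` cut flush at a [site]|[spacer] boundary,
    or None: needs the site to end with the first cut_top recognition bases."""
    t = enz.cut_top
    if t < 1 or t >= len(enz.recognition):
        return None
    if site_seq.endswith(enz.recognition[:t]):
        return enz.recognition[t:]
    return None


def _flush_right(site_seq: str, enz: EnzymeSpec) -> str | None:
    """Spacer suffix making ``enz`` cut flush at a [spacer]|[site] boundary,
    or None: needs the site to start with the last (len-cut_top) bases."""
    t = enz.cut_top
    if t < 1 or t >= len(enz.recognition):
        return None
    if site_seq.startswith(enz.recognition[t:]):
        return enz.recognition[:t]
    return None


@dataclass
class BackboneFixture:
    """A circular backbone plasmid and its expected digest behavior."""

    name: str
    plasmid_sequence: str  # circular, top strand
    backbone: Backbone     # the post-digest linearized backbone
    arch: BackboneArch
    released_length: int   # expected spacer fragment, bp
    backbone_length: int
    left_enzyme: str
    right_enzyme: str
    right_remnant: str     # non-empty when no flush geometry exists (see docs)


def generate_fixture_backbone(spec: FixtureSpec, name: str = "") -> BackboneFixture:
    """A circular plasmid whose declared enzymes release the spacer.

    The plasmid reads ``[start site][spacer][end site][vector]`` around the
    circle.  Each boundary is assigned a declared enzyme with flush cut
    geometry where one exists (both boundaries of a 1-5 or 2-5 architecture
    have one); a boundary with no flush option gets the recognition
    embedded at the spacer edge, leaving the post-cut remnant on the
    backbone terminus.  The released fragment always measures exactly
    ``spacer_length`` (cut-to-cut).
    """
    arch = spec.backbone_arch
    panel = load_enzyme_panel()
    for e in arch.enzymes:
        if e not in panel:
            raise FixtureError(f"releasing enzyme {e!r} not in the enzyme panel")
    enzymes = [panel[e] for e in arch.enzymes]
    start_site = SITE_SEQUENCES[arch.chain_start_site]
    end_site = SITE_SEQUENCES[arch.chain_end_site]

    left_opts = {e.name: _flush_left(start_site, e) for e in enzymes}
    right_opts = {e.name: _flush_right(end_site, e) for e in enzymes}
    left_opts = {k: v for k, v in left_opts.items() if v is not None}
    right_opts = {k: v for k, v in right_opts.items() if v is not None}
    if not left_opts:
        raise FixtureError(
            f"no declared enzyme cuts flush after site #{arch.chain_start_site}; "
            f"candidates: {', '.join(arch.enzymes)}"
        )
    # prefer an assignment that uses as many declared enzymes as possible
    left_name = next(iter(left_opts))
    right_name = next(iter(right_opts), None)
    for ln in left_opts:
        for rn in right_opts or [None]:
            if rn is not None and rn != ln:
                left_name, right_name = ln, rn
    spacer_prefix = left_opts[left_name]
    right_remnant = ""
    if right_name is not None:
        spacer_suffix = right_opts[right_name]
    else:
        # no flush geometry at the right boundary: embed the recognition at
        # the spacer edge; the post-cut tail stays on the backbone terminus
        fallback = next(e for e in enzymes if e.name != left_name) if len(enzymes) > 1 else enzymes[0]
        right_name = fallback.name
        spacer_suffix = fallback.recognition[: fallback.cut_top]
        right_remnant = fallback.recognition[fallback.cut_top :]

    rng = random.Random(spec.seed + 10_007)
    forbidden = spec.forbidden()
    spacer = _sample_clean(
        rng, arch.spacer_length, spec.gc_fraction, forbidden,
        prefix=spacer_prefix, suffix=spacer_suffix,
    )
    for attempt in range(1000):
        vector = _sample_clean(rng, spec.vector_length, spec.gc_fraction, forbidden)
        plasmid = start_site + spacer + right_remnant + end_site + vector
        result = digest(plasmid, enzymes, circular=True)
        left_cut = len(start_site)
        right_cut = left_cut + arch.spacer_length
        if set(result.cut_positions) == {left_cut, right_cut}:
            break
    else:
        raise FixtureError("could not build a plasmid with exactly the two intended cuts")

    backbone_seq = plasmid[right_cut:] + plasmid[:left_cut]
    fixture_name = name or (
        f"backbone_{arch.chain_start_site}-{arch.chain_end_site}_{'_'.join(arch.enzymes)}"
    )
    backbone = Backbone(
        name=fixture_name,
        sequence=backbone_seq,
        chain_start_site=arch.chain_start_site,
        chain_end_site=arch.chain_end_site,
        source_note=(
            f"synthetic fixture; released by {'+'.join(arch.enzymes)} from a "
            f"{len(plasmid)} bp plasmid with a {arch.spacer_length} bp spacer"
        ),
    )
    return BackboneFixture(
        name=fixture_name,
        plasmid_sequence=plasmid,
        backbone=backbone,
        arch=arch,
        released_length=arch.spacer_length,
        backbone_length=len(backbone_seq),
        left_enzyme=left_name,
        right_enzyme=right_name,
        right_remnant=right_remnant,
    )
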