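"""One-pot Gibson assembly simulation.

Gibson (isothermal) assembly joins DNA fragments that share terminal
homology: a 5' exonuclease chews back ends, complementary single strands
anneal, and polymerase + ligase seal the joint.  In silico this reduces to
exact suffix/prefix matching between fragment termini: the platform's
designed 30-mer overlap sites make junctions unambiguous by construction,
so overlap detection here is exact-match (no mismatches) with a
configurable minimum length, default 30 nt (the designed site length;
the underlying chemistry tolerates roughly 30-40 bp).

Thermodynamics and reaction kinetics are deliberately not modeled; the
output is the set of circular sequences the fragment termini can close.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product as iproduct

from .errors import AmbiguousAssemblyError, GmapError, IncompleteAssemblyError
from .registry import SITE_LENGTH, SITE_SEQUENCES
from .sequences import canonical_circular, clean_sequence, revcomp

DEFAULT_MIN_OVERLAP = 30


@dataclass(frozen=True)
class GraphEdge:
    """Directed junction candidate between two oriented fragments."""

    upstream: str
    upstream_orientation: str  # '+' forward, '-' reverse complement
    downstream: str
    downstream_orientation: str
    overlap_length: int
    site_id: int | None


@dataclass
class Junction:
    """A realized fusion point in an assembled circle."""

    upstream: str
    downstream: str
    overlap_length: int
    downstream_orientation: str
    site_id: int | None
    position_in_product: int  # 0-based start of the overlap in the product


@dataclass
class AssemblyProduct:
    """A circular construct: sequence, fragment order, annotated junctions."""

    sequence: str
    fragment_order: list[tuple[str, str]]  # (fragment name, orientation)
    junctions: list[Junction]
    total_length: int

    def canonical_sequence(self) -> str:
        return canonical_circular(self.sequence)


@dataclass
class EnumerationResult:
    products: list[AssemblyProduct]
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.products)

    def __iter__(self):
        return iter(self.products)


def _normalize(fragments) -> list[tuple[str, str]]:
    """Accept a dict name->seq, list of (name, seq) pairs, or Part/Backbone
    objects; return [(name, upper-seq)]."""
    out = []
    items = fragments.items() if isinstance(fragments, dict) else fragments
    for item in items:
        if isinstance(item, tuple):
            name, seq = item
        elif hasattr(item, "flanked_sequence"):
            name, seq = item.name, item.flanked_sequence
        elif hasattr(item, "sequence"):
            name, seq = item.name, item.sequence
        else:
            raise GmapError(f"cannot interpret fragment {item!r}")
        out.append((name, clean_sequence(seq, what=f"fragment {name}")))
    names = [n for n, _ in out]
    if len(set(names)) != len(names):
        raise GmapError(f"duplicate fragment names: {names}")
    return out


def _oriented(seq: str, orientation: str) -> str:
    return seq if orientation == "+" else revcomp(seq)


def _site_id_of(overlap: str) -> int | None:
    if len(overlap) != SITE_LENGTH:
        return None
    for sid, s in SITE_SEQUENCES.items():
        if overlap == s:
            return sid
    return None


def _longest_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest k >= min_overlap with suffix(a, k) == prefix(b, k)."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


def find_junctions(fragments, min_overlap: int = DEFAULT_MIN_OVERLAP) -> list[GraphEdge]:
    """Junction graph: terminal homologies between all oriented fragment pairs.

    For every ordered pair of distinct fragments and every orientation
    combination, records the longest suffix-of-upstream == prefix-of-
    downstream match of length >= ``min_overlap``.  A fragment used in '-'
    orientation contributes its reverse complement's termini.
    """
    if min_overlap < 15:
        raise GmapError(f"min_overlap must be >= 15, got {min_overlap}")
    frags = _normalize(fragments)
    if len(frags) < 2:
        raise GmapError("need at least 2 fragments to find junctions")
    edges: list[GraphEdge] = []
    for (na, sa), (nb, sb) in permutations(frags, 2):
        for oa, ob in iproduct("+-", repeat=2):
            k = _longest_overlap(_oriented(sa, oa), _oriented(sb, ob), min_overlap)
            if k:
                overlap = _oriented(sb, ob)[:k]
                edges.append(GraphEdge(na, oa, nb, ob, k, _site_id_of(overlap)))
    return edges


def _edge_lookup(edges: list[GraphEdge]):
    table: dict[tuple[str, str], list[GraphEdge]] = {}
    for e in edges:
        table.setdefault((e.upstream, e.upstream_orientation), []).append(e)
    return table


def _build_product(
    frags: dict[str, str],
    order: list[tuple[str, str]],
    overlaps: list[int],
) -> AssemblyProduct:
    """Concatenate oriented fragments, collapsing each overlap once; the
    final overlap closes the circle back onto the first fragment."""
    seqs = [_oriented(frags[n], o) for n, o in order]
    product_seq = seqs[0]
    junctions: list[Junction] = []
    pos = len(seqs[0])
    for i in range(1, len(order)):
        k = overlaps[i - 1]
        junctions.append(
            Junction(
                upstream=order[i - 1][0],
                downstream=order[i][0],
                overlap_length=k,
                downstream_orientation=order[i][1],
                site_id=_site_id_of(seqs[i][:k]),
                position_in_product=pos - k,
            )
        )
        product_seq += seqs[i][k:]
        pos = len(product_seq)
    k_close = overlaps[-1]
    junctions.append(
        Junction(
            upstream=order[-1][0],
            downstream=order[0][0],
            overlap_length=k_close,
            downstream_orientation=order[0][1],
            site_id=_site_id_of(seqs[0][:k_close]),
            position_in_product=len(product_seq) - k_close,
        )
    )
    product_seq = product_seq[:-k_close]
    total = sum(len(s) for s in seqs) - sum(overlaps)
    assert total == len(product_seq)
    return AssemblyProduct(
        sequence=product_seq,
        fragment_order=list(order),
        junctions=junctions,
        total_length=total,
    )


def _find_cycles(
    frags: dict[str, str],
    edges: list[GraphEdge],
    start: tuple[str, str],
    require_all: bool,
    allowed: set[str] | None = None,
    max_cycles: int = 10_000,
) -> list[AssemblyProduct]:
    """All simple cycles through the junction graph beginning at ``start``;
    each fragment used at most once (exactly once each when require_all)."""
    table = _edge_lookup(edges)
    cycles: list[AssemblyProduct] = []
    n_total = len(allowed) + 1 if allowed is not None else len(frags)

    def walk(node: tuple[str, str], path: list[tuple[str, str]], ovls: list[int]):
        if len(cycles) >= max_cycles:
            return
        for e in table.get(node, []):
            nxt = (e.downstream, e.downstream_orientation)
            if e.downstream == start[0]:
                if nxt == start and len(path) >= 2:
                    if not require_all or len(path) == n_total:
                        cycles.append(_build_product(frags, path, ovls + [e.overlap_length]))
                continue
            if allowed is not None and e.downstream not in allowed:
                continue
            if any(e.downstream == n for n, _ in path):
                continue
            walk(nxt, path + [nxt], ovls + [e.overlap_length])

    walk(start, [start], [])
    return cycles


def _dedupe(products: list[AssemblyProduct]) -> list[AssemblyProduct]:
    seen: dict[str, AssemblyProduct] = {}
    for p in products:
        seen.setdefault(p.canonical_sequence(), p)
    return list(seen.values())


def _unmatched_site_diagnostic(frags: dict[str, str]) -> list[int]:
    """Site ids whose terminal occurrences don't pair up across fragments."""
    starts: dict[int, int] = {}
    ends: dict[int, int] = {}
    for seq in frags.values():
        s = _site_id_of(seq[:SITE_LENGTH])
        e = _site_id_of(seq[-SITE_LENGTH:])
        if s is not None:
            starts[s] = starts.get(s, 0) + 1
        if e is not None:
            ends[e] = ends.get(e, 0) + 1
    return sorted(
        sid for sid in set(starts) | set(ends) if starts.get(sid, 0) != ends.get(sid, 0)
    )


def assemble(
    fragments, backbone, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> AssemblyProduct:
    """The unique circular product the fragment pool can close with the
    backbone.

    The product is rotated to start at the backbone's first base with the
    backbone in forward orientation.  Raises
    :class:`IncompleteAssemblyError` (naming unmatched terminal sites) when
    no circle closes, and :class:`AmbiguousAssemblyError` when more than
    one distinct product is possible.
    """
    bb = _normalize([backbone])[0]
    frags = dict(_normalize(fragments))
    if bb[0] in frags:
        raise GmapError(f"backbone name {bb[0]!r} collides with a fragment")
    all_frags = {bb[0]: bb[1], **frags}
    edges = find_junctions(list(all_frags.items()), min_overlap)
    # one-pot semantics: any sub-multiset of the supplied fragments may close
    # with the backbone, so a competing duplicate part is an ambiguity, not
    # a failure to use everything
    cycles = _find_cycles(all_frags, edges, start=(bb[0], "+"), require_all=False)
    products = _dedupe(cycles)
    if not products:
        unmatched = _unmatched_site_diagnostic(all_frags)
        raise IncompleteAssemblyError(
            "no circular assembly closes; unmatched terminal site(s): "
            + (", ".join(f"#{s}" for s in unmatched) if unmatched else "none identifiable"),
            unmatched,
        )
    if len(products) > 1:
        raise AmbiguousAssemblyError(
            f"{len(products)} distinct circular products are possible; "
            "fragment set is ambiguous",
            products,
        )
    product = products[0]
    _warn_internal_homology(all_frags, product)
    return product


def _warn_internal_homology(frags: dict[str, str], product: AssemblyProduct) -> None:
    """Attach warnings for terminal 30-mers that also occur internally
    (potential misassembly source); stored on the product."""
    warnings: list[str] = []
    for name, seq in frags.items():
        for label, terminal in (("start", seq[:SITE_LENGTH]), ("end", seq[-SITE_LENGTH:])):
            interior = seq[1:-1]
            if terminal in interior:
                warnings.append(
                    f"fragment {name}: terminal 30-mer at its {label} also occurs internally"
                )
    product.internal_homology_warnings = warnings  # type: ignore[attr-defined]


def enumerate_products(
    fragments, min_overlap: int = DEFAULT_MIN_OVERLAP, max_products: int = 100
) -> EnumerationResult:
    """All distinct circles formable from any sub-multiset of fragments.

    Each fragment is used at most once; products are deduplicated up to
    rotation and reverse complement and capped at ``max_products`` (the
    ``truncated`` flag is set instead of raising).
    """
    if max_products < 1:
        raise GmapError(f"max_products must be >= 1, got {max_products}")
    frags = dict(_normalize(fragments)) if fragments else {}
    if len(frags) < 2:
        return EnumerationResult([], False)
    edges = find_junctions(list(frags.items()), min_overlap)
    names = list(frags)
    all_products: list[AssemblyProduct] = []
    for i, name in enumerate(names):
        higher = set(names[i + 1 :])
        all_products.extend(
            _find_cycles(frags, edges, start=(name, "+"), require_all=False, allowed=higher)
        )
    products = _dedupe(all_products)
    products.sort(key=lambda p: (p.total_length, p.canonical_sequence()))
    if len(products) > max_products:
        return EnumerationResult(products[:max_products], True)
    return EnumerationResult(products, False)
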