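"""Junction detection, circular assembly, and product enumeration."""

import random
from itertools import permutations, product as iproduct

import pytest

from gmapkit.assembly import (
    _longest_overlap,
    assemble,
    enumerate_products,
    find_junctions,
)
from gmapkit.errors import (
    AmbiguousAssemblyError,
    GmapError,
    IncompleteAssemblyError,
)
from gmapkit.registry import SITE_SEQUENCES, make_flanked_part
from gmapkit.sequences import canonical_circular, revcomp

from conftest import rand_dna


class TestFindJunctions:
    def test_shared_site_yields_forward_edge_with_site_id(self):
        rng = random.Random(0)
        a = rand_dna(rng, 50) + SITE_SEQUENCES[2]
        b = SITE_SEQUENCES[2] + rand_dna(rng, 50)
        edges = find_junctions([("A", a), ("B", b)])
        fwd = [e for e in edges if (e.upstream, e.downstream) == ("A", "B")
               and (e.upstream_orientation, e.downstream_orientation) == ("+", "+")]
        assert len(fwd) == 1
        assert fwd[0].overlap_length == 30
        assert fwd[0].site_id == 2

    def test_reverse_complemented_downstream_detected(self):
        rng = random.Random(1)
        a = rand_dna(rng, 50) + SITE_SEQUENCES[2]
        b = SITE_SEQUENCES[2] + rand_dna(rng, 50)
        edges = find_junctions([("A", a), ("B", revcomp(b))])
        hit = [e for e in edges if (e.upstream, e.upstream_orientation) == ("A", "+")
               and e.downstream == "B"]
        assert hit and hit[0].downstream_orientation == "-"
        # brute-force over the 4 orientation combinations agrees
        combos = [
            (oa, ob)
            for oa, ob in iproduct("+-", repeat=2)
            if _longest_overlap(
                a if oa == "+" else revcomp(a),
                revcomp(b) if ob == "+" else b, 30)
        ]
        assert ("+", "-") in combos

    def test_unrelated_fragments_give_empty_graph(self):
        assert find_junctions([("A", rand_dna(random.Random(2), 60)),
                               ("B", rand_dna(random.Random(3), 60))]) == []

    def test_preconditions(self):
        with pytest.raises(GmapError):
            find_junctions([("A", "ACGT" * 20)])
        with pytest.raises(GmapError):
            find_junctions([("A", "ACGT" * 20), ("B", "ACGT" * 20)], min_overlap=10)


class TestAssemble:
    def test_four_part_product_conserves_length(self, parts_by_slot, backbone_fixture):
        frags = [parts_by_slot[s] for s in ("pA", "gA", "pB", "gB")]
        product = assemble(frags, backbone_fixture.backbone)
        expected = sum(len(f) for f in frags) + len(backbone_fixture.backbone) - 5 * 30
        assert product.total_length == expected == len(product.sequence)

    def test_junction_sites_ascend_around_the_circle(self, four_part_product):
        assert [j.site_id for j in four_part_product.junctions] == [1, 2, 3, 4, 5]
        positions = [j.position_in_product for j in four_part_product.junctions]
        assert positions == sorted(positions)

    def test_product_starts_at_backbone_first_base(self, four_part_product, backbone_fixture):
        assert four_part_product.sequence.startswith(
            backbone_fixture.backbone.sequence[:100]
        )
        assert four_part_product.fragment_order[0][0] == backbone_fixture.backbone.name

    def test_missing_part_reports_unmatched_sites(self, parts_by_slot, backbone_fixture):
        frags = [parts_by_slot[s] for s in ("pA", "gA", "gB")]  # pB missing
        with pytest.raises(IncompleteAssemblyError) as exc:
            assemble(frags, backbone_fixture.backbone)
        assert exc.value.unmatched_sites == [3, 4]

    def test_second_competing_part_is_ambiguous(self, parts_by_slot, backbone_fixture):
        rng = random.Random(42)
        extra_gB = make_flanked_part(rand_dna(rng, 200), "gB", name="gB_alt")
        frags = [parts_by_slot[s] for s in ("pA", "gA", "pB", "gB")] + [extra_gB]
        with pytest.raises(AmbiguousAssemblyError) as exc:
            assemble(frags, backbone_fixture.backbone)
        assert len(exc.value.products) == 2

    def test_two_part_design_assembles(self, parts_by_slot, backbone_fixture):
        product = assemble(
            [parts_by_slot["pA"], parts_by_slot["gC"]], backbone_fixture.backbone
        )
        assert [j.site_id for j in product.junctions] == [1, 2, 5]

    def test_shuffle_and_strand_flips_yield_identical_canonical_product(
        self, parts_by_slot, backbone_fixture
    ):
        frags = [parts_by_slot[s] for s in ("pA", "gA", "pB", "gB")]
        reference = assemble(frags, backbone_fixture.backbone).canonical_sequence()
        rng = random.Random(99)
        for _ in range(6):
            shuffled = list(frags)
            rng.shuffle(shuffled)
            flipped = [
                (f.name, revcomp(f.flanked_sequence)) if rng.random() < 0.5
                else (f.name, f.flanked_sequence)
                for f in shuffled
            ]
            product = assemble(flipped, backbone_fixture.backbone)
            assert product.canonical_sequence() == reference


def naive_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest suffix(a) == prefix(b), written independently of the package."""
    best = 0
    for k in range(min_overlap, min(len(a), len(b)) + 1):
        if a[len(a) - k:] == b[:k]:
            best = k
    return best


def brute_force_circles(fragments: dict[str, str], min_overlap: int) -> set[str]:
    """Oracle: all distinct circular products over permutations of subsets
    and all orientation assignments, deduplicated by canonical sequence."""
    oriented = {
        (n, o): (s if o == "+" else revcomp(s))
        for n, s in fragments.items() for o in "+-"
    }
    table = {
        (ka, kb): naive_overlap(sa, sb, min_overlap)
        for ka, sa in oriented.items() for kb, sb in oriented.items()
        if ka[0] != kb[0]
    }
    names = list(fragments)
    found = set()
    for r in range(2, len(names) + 1):
        for perm in permutations(names, r):
            for orients in iproduct("+-", repeat=r):
                keys = list(zip(perm, orients))
                ovls = []
                ok = True
                for i in range(r):
                    k = table[(keys[i], keys[(i + 1) % r])]
                    if not k:
                        ok = False
                        break
                    ovls.append(k)
                if not ok:
                    continue
                seqs = [oriented[key] for key in keys]
                circle = "".join(s[ovls[i - 1]:] for i, s in enumerate(seqs))
                assert len(circle) == sum(map(len, seqs)) - sum(ovls)
                found.add(canonical_circular(circle))
    return found


class TestEnumerateProducts:
    def test_single_closing_set_yields_one_product(self, parts_by_slot, backbone_fixture):
        frags = [parts_by_slot[s] for s in ("pA", "gC")]
        pool = [(f.name, f.flanked_sequence) for f in frags] + [
            (backbone_fixture.backbone.name, backbone_fixture.backbone.sequence)
        ]
        result = enumerate_products(pool)
        assert len(result) == 1 and not result.truncated

    def test_matches_brute_force_on_contrived_set(self, parts_by_slot, backbone_fixture):
        pool = {
            p.name: p.flanked_sequence
            for p in (parts_by_slot["pA"], parts_by_slot["gA"], parts_by_slot["gB"],
                      parts_by_slot["gC"], parts_by_slot["pC"])
        }
        pool[backbone_fixture.backbone.name] = backbone_fixture.backbone.sequence
        result = enumerate_products(list(pool.items()))
        got = {p.canonical_sequence() for p in result}
        assert got == brute_force_circles(pool, 30)
        assert len(got) == 2  # pA:gC and pC:gB close; pA:gA stalls without pB

    def test_empty_input_gives_empty_list(self):
        assert len(enumerate_products([])) == 0

    def test_cap_sets_truncation_flag(self, parts_by_slot, backbone_fixture):
        pool = [(p.name, p.flanked_sequence) for p in parts_by_slot.values()]
        pool.append((backbone_fixture.backbone.name, backbone_fixture.backbone.sequence))
        capped = enumerate_products(pool, max_products=1)
        assert capped.truncated and len(capped) == 1
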