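"""Synthetic fixture generation, file round-trips, and the CLI surface."""

import random

import pytest
from click.testing import CliRunner

from gmapkit.cli import main as cli_main
from gmapkit.digest import digest, load_enzyme_panel
from gmapkit.errors import FixtureError, FormatError
from gmapkit.fixtures import (
    BackboneArch,
    FixtureSpec,
    generate_fixture_backbone,
    generate_fixture_parts,
)
from gmapkit.registry import SITE_SEQUENCES, classify_fragment, validate_part
from gmapkit.seqio import (
    read_registry,
    read_sequences,
    write_fasta,
    write_product_genbank,
    write_registry,
)

PANEL = load_enzyme_panel()


class TestFixtureParts:
    def test_identical_seed_gives_byte_identical_parts(self):
        spec = FixtureSpec(seed=1, core_length_range=(100, 300))
        a = generate_fixture_parts(spec)
        b = generate_fixture_parts(spec)
        assert [(p.name, p.flanked_sequence) for p in a] == [
            (p.name, p.flanked_sequence) for p in b
        ]

    def test_different_seed_differs(self):
        a = generate_fixture_parts(FixtureSpec(seed=1, core_length_range=(100, 200)))
        b = generate_fixture_parts(FixtureSpec(seed=2, core_length_range=(100, 200)))
        assert a[0].flanked_sequence != b[0].flanked_sequence

    def test_cores_clean_so_validation_emits_no_warnings(self, parts):
        for p in parts:
            report = validate_part(p)
            assert report.passed
            assert report.warnings == []

    def test_three_promoters_three_genes_classify_to_declared_slots(self, parts):
        assert len(parts) == 6
        for p in parts:
            assert classify_fragment(p.flanked_sequence) == p.slot

    def test_unsatisfiable_forbid_list_fails_loudly(self):
        spec = FixtureSpec(
            seed=3, core_length_range=(50, 60),
            forbid_internal=("A", "C", "G", "T"),
        )
        with pytest.raises(FixtureError):
            generate_fixture_parts(spec)


class TestFixtureBackbone:
    @pytest.mark.parametrize(
        "arch",
        [
            BackboneArch(1, 5, 469, ("PmeI", "BsrGI")),
            BackboneArch(2, 5, 389, ("PmeI",)),
            BackboneArch(1, 4, 361, ("PmeI", "NheI")),
        ],
        ids=["LV-1-5", "RV-2-5", "TOPO-1-4"],
    )
    def test_digest_releases_the_declared_spacer_length(self, arch):
        fx = generate_fixture_backbone(FixtureSpec(seed=5, backbone_arch=arch))
        res = digest(
            fx.plasmid_sequence, [PANEL[e] for e in arch.enzymes], circular=True
        )
        assert arch.spacer_length in res.fragment_lengths
        assert sum(res.fragment_lengths) == len(fx.plasmid_sequence)

    @pytest.mark.parametrize("arch", [
        BackboneArch(1, 5, 469, ("PmeI", "BsrGI")),
        BackboneArch(2, 5, 389, ("PmeI",)),
    ], ids=["LV-1-5", "RV-2-5"])
    def test_linearized_backbone_keeps_sites_terminal(self, arch):
        fx = generate_fixture_backbone(FixtureSpec(seed=6, backbone_arch=arch))
        bb = fx.backbone.sequence
        assert bb.startswith(SITE_SEQUENCES[arch.chain_end_site])
        assert bb.endswith(SITE_SEQUENCES[arch.chain_start_site])

    def test_site1_spacer_junction_reconstitutes_pmei(self):
        # ...GGTTT | AAAC... across a site-ending-in-GTTT boundary
        assert (SITE_SEQUENCES[1][-4:] + "AAAC") == "GTTTAAAC"
        fx = generate_fixture_backbone(
            FixtureSpec(seed=7, backbone_arch=BackboneArch(2, 5, 389, ("PmeI",)))
        )
        junction = fx.plasmid_sequence[26:38]
        assert "GTTTAAAC" in junction

    def test_spacer_too_short_rejected(self):
        with pytest.raises(FixtureError):
            generate_fixture_backbone(
                FixtureSpec(seed=8, backbone_arch=BackboneArch(1, 5, 6, ("PmeI",)))
            )


class TestSequenceIO:
    def test_genbank_product_roundtrip(self, four_part_product, tmp_path):
        path = tmp_path / "product.gb"
        write_product_genbank(four_part_product, path, name="assembly")
        rec = read_sequences(path, "genbank")[0]
        assert str(rec.seq) == four_part_product.sequence
        # one feature per junction + one per source fragment
        assert len(rec.features) == 2 * len(four_part_product.fragment_order)
        assert rec.annotations["topology"] == "circular"

    def test_fasta_roundtrip_preserves_sequence(self, parts, tmp_path):
        path = tmp_path / "parts.fasta"
        write_fasta(parts, path)
        records = read_sequences(path, "fasta")
        assert [str(r.seq) for r in records] == [p.flanked_sequence for p in parts]

    def test_illegal_character_names_the_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">rec1\nACGTACGT\nACGTNACGT\n")
        with pytest.raises(FormatError) as exc:
            read_sequences(path, "fasta")
        assert exc.value.line == 3

    def test_empty_file_returns_empty_list(self, tmp_path, caplog):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_sequences(path, "fasta") == []

    def test_registry_roundtrip(self, parts, tmp_path):
        write_registry(parts, tmp_path / "registry")
        back = read_registry(tmp_path / "registry")
        assert [(p.name, p.slot, p.flanked_sequence) for p in back] == [
            (p.name, p.slot, p.flanked_sequence) for p in parts
        ]


class TestCli:
    def run(self, *args, **kw):
        return CliRunner().invoke(cli_main, list(args), **kw)

    def test_fills_prints_the_three_designs(self):
        result = self.run("parts", "fills", "--start", "1", "--end", "5")
        assert result.exit_code == 0
        assert result.output.splitlines() == ["pA:gC", "pC:gB", "pA:gA:pB:gB"]

    def test_reaction_colonies_prints_three(self):
        result = self.run("reaction", "colonies", "--p", "0.8", "--confidence", "0.99")
        assert result.exit_code == 0
        assert result.output.strip() == "3"

    def test_unknown_subcommand_is_usage_error(self):
        assert self.run("frobnicate").exit_code == 2

    def test_fixture_assemble_digest_pipeline(self, tmp_path):
        fx = tmp_path / "fx"
        result = self.run("--seed", "5", "fixtures", "--outdir", str(fx))
        assert result.exit_code == 0, result.output
        # keep only the four-fragment design's parts
        records = read_sequences(fx / "parts.fasta", "fasta")
        keep = [r for r in records if r.id.split("_")[1] in ("pA", "gA", "pB", "gB")]
        write_fasta([(r.id, str(r.seq)) for r in keep], fx / "four.fasta")
        out = tmp_path / "product.gb"
        result = self.run(
            "assemble", "--backbone", str(fx / "backbone_linear.fasta"),
            "--parts", str(fx / "four.fasta"), "--out", str(out),
        )
        assert result.exit_code == 0, result.output
        assert "junction sites 1,2,3,4,5" in result.output
        result = self.run("digest", "--in", str(out), "--enzymes", "NheI,AvrII")
        assert result.exit_code == 0
        bands = result.output.strip().split("\t")[-1].split(",")
        assert len(bands) == 2  # NheI (site 2) + AvrII (site 3) each cut once

    def test_assemble_with_missing_part_names_the_gap(self, tmp_path):
        fx = tmp_path / "fx"
        assert self.run("--seed", "5", "fixtures", "--outdir", str(fx)).exit_code == 0
        records = read_sequences(fx / "parts.fasta", "fasta")
        keep = [r for r in records if r.id.split("_")[1] in ("pA", "gA", "gB")]
        write_fasta([(r.id, str(r.seq)) for r in keep], fx / "gap.fasta")
        result = self.run(
            "assemble", "--backbone", str(fx / "backbone_linear.fasta"),
            "--parts", str(fx / "gap.fasta"),
        )
        assert result.exit_code == 1
        assert "#3" in result.output and "#4" in result.output

    def test_pipeline_deterministic_across_seeds(self, tmp_path):
        rng = random.Random(0)
        for seed in [rng.randint(0, 10_000) for _ in range(3)]:
            a = tmp_path / f"a{seed}"
            b = tmp_path / f"b{seed}"
            assert self.run("--seed", str(seed), "fixtures", "--outdir", str(a)).exit_code == 0
            assert self.run("--seed", str(seed), "fixtures", "--outdir", str(b)).exit_code == 0
            assert (a / "parts.fasta").read_text() == (b / "parts.fasta").read_text()
            assert (a / "backbone_plasmid.fasta").read_text() == (
                b / "backbone_plasmid.fasta"
            ).read_text()
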