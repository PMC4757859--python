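"""FASTA/GenBank readers and writers.

Thin wrappers over Bio.SeqIO that enforce the package's DNA alphabet
(errors name the offending line for FASTA input) and annotate assembly
products as circular GenBank records with one ``misc_feature`` per
junction and per source fragment — maximally portable feature keys.

A part registry persists as FASTA (one record per part, flanked sequence)
plus a tab-delimited index (name, role, slot, core length, warnings).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .assembly import AssemblyProduct, Junction
from .errors import FormatError
from .registry import Part
from .sequences import DNA_ALPHABET

logger = logging.getLogger("gmapkit")

_FORMATS = {"fasta", "genbank"}
_SUFFIXES = {".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
             ".gb": "genbank", ".gbk": "genbank", ".genbank": "genbank"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        f = fmt.lower()
        if f not in _FORMATS:
            raise FormatError(f"unknown sequence format {fmt!r}; use fasta or genbank")
        return f
    f = _SUFFIXES.get(path.suffix.lower())
    if f is None:
        raise FormatError(f"cannot infer format from suffix {path.suffix!r}")
    return f


def _find_bad_fasta_line(path: Path) -> tuple[int, str] | None:
    """(1-based line, offending char) of the first non-ACGT sequence char."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") or line.startswith(";"):
                continue
            for ch in line.strip():
                if ch.upper() not in DNA_ALPHABET:
                    return lineno, ch
    return None


def read_sequences(path, fmt: str | None = None) -> list[SeqRecord]:
    """Read a multi-record FASTA or GenBank file, validating the alphabet.

    Empty files return an empty list with a logged warning; a malformed
    FASTA raises :class:`FormatError` naming the line.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:
        raise FormatError(f"malformed {fmt} file {path}: {exc}") from exc
    if not records:
        logger.warning("no records in %s", path)
        return []
    for rec in records:
        bad = next((ch for ch in str(rec.seq).upper() if ch not in DNA_ALPHABET), None)
        if bad is not None:
            if fmt == "fasta":
                found = _find_bad_fasta_line(path)
                if found:
                    raise FormatError(
                        f"{path}: illegal character {found[1]!r} on line {found[0]}",
                        line=found[0],
                    )
            raise FormatError(
                f"{path}: record {rec.id} contains illegal character {bad!r}"
            )
        rec.seq = Seq(str(rec.seq).upper())
    return records


def write_fasta(records, path) -> None:
    """Write (name, sequence) pairs, Parts, or SeqRecords as FASTA."""
    out = []
    for item in records:
        if isinstance(item, SeqRecord):
            out.append(item)
        elif isinstance(item, Part):
            out.append(SeqRecord(Seq(item.flanked_sequence), id=item.name, description=f"slot={item.slot}"))
        else:
            name, seq = item
            out.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(out, str(path), "fasta")


def _fragment_locations(product: AssemblyProduct) -> list[tuple[str, str, int, int]]:
    """(name, orientation, start, end) spans of each source fragment in
    product coordinates; the last fragment's end exceeds the product length
    by the closing overlap (it wraps the origin)."""
    spans = []
    for i, (name, orient) in enumerate(product.fragment_order):
        start = 0 if i == 0 else product.junctions[i - 1].position_in_product
        j: Junction = product.junctions[i]
        spans.append((name, orient, start, j.position_in_product + j.overlap_length))
    return spans


def _circular_location(start: int, end: int, length: int, strand: int):
    """Feature location on a circular record, split when spanning the origin."""
    s = start % length
    e = end - (start - s)
    if e <= length:
        return SimpleLocation(s, e, strand=strand)
    return CompoundLocation(
        [SimpleLocation(s, length, strand=strand), SimpleLocation(0, e - length, strand=strand)]
    )


def product_to_seqrecord(product: AssemblyProduct, name: str = "assembly") -> SeqRecord:
    """Circular GenBank-ready record with junction and fragment features."""
    rec = SeqRecord(Seq(product.sequence), id=name[:16] or "assembly", name=name[:16] or "assembly",
                    description=f"in-silico assembly, {product.total_length} bp")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    L = product.total_length
    for junc in product.junctions:
        loc = _circular_location(
            junc.position_in_product, junc.position_in_product + junc.overlap_length, L, 1
        )
        note = f"junction {junc.upstream}->{junc.downstream}, overlap {junc.overlap_length} bp"
        if junc.site_id is not None:
            note += f", overlap site #{junc.site_id}"
        feat = SeqFeature(loc, type="misc_feature", qualifiers={"note": [note]})
        if junc.site_id is not None:
            feat.qualifiers["label"] = [f"site_{junc.site_id}"]
        rec.features.append(feat)
    for name_, orient, start, end in _fragment_locations(product):
        loc = _circular_location(start, end, L, 1 if orient == "+" else -1)
        rec.features.append(
            SeqFeature(loc, type="misc_feature",
                       qualifiers={"note": [f"fragment {name_} ({orient})"], "label": [name_]})
        )
    return rec


def write_product_genbank(product: AssemblyProduct, path, name: str = "assembly") -> None:
    SeqIO.write([product_to_seqrecord(product, name)], str(path), "genbank")


# ---------------------------------------------------------------------------
# part registry persistence


def write_registry(parts: list[Part], directory) -> tuple[Path, Path]:
    """Persist parts as FASTA + TSV index; returns (fasta path, index path)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "parts.fasta"
    index = directory / "parts.tsv"
    write_fasta(parts, fasta)
    pd.DataFrame(
        [
            {
                "name": p.name,
                "role": p.role,
                "slot": p.slot,
                "core_length": len(p.core_sequence),
                "warnings": "; ".join(p.warnings),
            }
            for p in parts
        ]
    ).to_csv(index, sep="\t", index=False)
    return fasta, index


def read_registry(directory) -> list[Part]:
    """Load a persisted registry back into Part objects."""
    from .registry import SITE_LENGTH, classify_fragment, slot_role

    directory = Path(directory)
    records = read_sequences(directory / "parts.fasta", "fasta")
    index = pd.read_csv(directory / "parts.tsv", sep="\t").set_index("name")
    parts = []
    for rec in records:
        seq = str(rec.seq)
        slot = index.loc[rec.id, "slot"] if rec.id in index.index else classify_fragment(seq)
        warnings = index.loc[rec.id, "warnings"] if rec.id in index.index else ""
        parts.append(
            Part(
                name=rec.id,
                role=slot_role(slot),
                slot=slot,
                core_sequence=seq[SITE_LENGTH:-SITE_LENGTH],
                flanked_sequence=seq,
                warnings=[w for w in str(warnings).split("; ") if w and w != "nan"],
            )
        )
    return parts
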