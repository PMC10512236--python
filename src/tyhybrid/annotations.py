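"""Genomic features, TE annotation records and FASTA/GFF3/GTF input-output.

Coordinates are 0-based half-open everywhere in memory; conversion to the
1-based closed convention happens only when reading or writing GFF3/GTF.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TE_PARTS = ("internal", "LTR")


@dataclasses.dataclass(frozen=True)
class Feature:
    """A genomic interval with a type and free-form attributes.

    ``start``/``end`` are 0-based half-open positions on ``contig``.
    """

    contig: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "transcript"
    attrs: tuple = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def attr(self, key: str, default=None):
        for k, v in self.attrs:
            if k == key:
                return v
        return default

    def with_attrs(self, **kwargs) -> "Feature":
        merged = dict(self.attrs)
        merged.update(kwargs)
        return dataclasses.replace(self, attrs=tuple(sorted(merged.items())))

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def make_feature(contig, start, end, strand="+", kind="transcript", **attrs) -> Feature:
    return Feature(contig, start, end, strand, kind, tuple(sorted(attrs.items())))


@dataclasses.dataclass(frozen=True)
class TeAnnotationRecord:
    """One annotated TE interval: an internal sequence or an LTR.

    ``element_id`` groups the parts (5' LTR, internal, 3' LTR) of one
    full-length element; solo LTRs carry their own element_id.
    """

    contig: str
    start: int
    end: int
    strand: str
    family: str
    part: str
    element_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid TE interval [{self.start}, {self.end})")
        if self.part not in TE_PARTS:
            raise ValueError(f"part must be one of {TE_PARTS}, got {self.part!r}")
        if not self.family:
            raise ValueError("family must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3 / GTF

_GFF_COLS = 9


def _fmt_attrs_gff3(attrs: Iterable[tuple]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs) or "."


def _fmt_attrs_gtf(attrs: Iterable[tuple]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs) or "."


def write_features(features: Iterable[Feature], path, fmt: str = "gff3",
                   source: str = "tyhybrid") -> None:
    """Write features as GFF3 or GTF (1-based closed coordinates)."""
    fmt_attrs = _fmt_attrs_gff3 if fmt == "gff3" else _fmt_attrs_gtf
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        source,
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        fmt_attrs(f.attrs),
                    ]
                )
                + "\n"
            )


def _parse_attrs(field: str) -> dict:
    attrs: dict = {}
    field = field.strip()
    if not field or field == ".":
        return attrs
    if "=" in field.split(";")[0] and '"' not in field:
        for part in field.split(";"):  # GFF3 style key=value
            part = part.strip()
            if part and "=" in part:
                k, v = part.split("=", 1)
                attrs[k] = v
    else:  # GTF style key "value";
        for part in field.split(";"):
            part = part.strip()
            if not part:
                continue
            bits = part.split(None, 1)
            if len(bits) == 2:
                attrs[bits[0]] = bits[1].strip('"')
    return attrs


def read_features(path) -> list[Feature]:
    """Read GFF3 or GTF into a list of :class:`Feature` (0-based half-open)."""
    out: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != _GFF_COLS:
                continue
            attrs = _parse_attrs(cols[8])
            out.append(
                Feature(
                    contig=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in ("+", "-") else "+",
                    kind=cols[2],
                    attrs=tuple(sorted(attrs.items())),
                )
            )
    return out


def read_te_annotations(path, family_key: str = "family", part_key: str = "part",
                        element_key: str = "element_id") -> list[TeAnnotationRecord]:
    """Read TE annotations from GFF3/GTF; attribute keys are configurable."""
    records = []
    for f in read_features(path):
        family = f.attr(family_key)
        part = f.attr(part_key)
        if family is None or part is None:
            continue
        records.append(
            TeAnnotationRecord(
                contig=f.contig,
                start=f.start,
                end=f.end,
                strand=f.strand,
                family=family,
                part=part,
                element_id=f.attr(element_key, f"{family}:{f.contig}:{f.start}"),
            )
        )
    return records


def write_te_annotations(records: Iterable[TeAnnotationRecord], path) -> None:
    feats = [
        make_feature(
            r.contig, r.start, r.end, r.strand,
            kind="mobile_element" if r.part == "internal" else "long_terminal_repeat",
            family=r.family, part=r.part, element_id=r.element_id,
        )
        for r in records
    ]
    write_features(feats, path, fmt="gff3")


def features_to_path_or_list(annotation) -> list[Feature]:
    """Accept either a list of Features or a GFF/GTF path."""
    if isinstance(annotation, (str, Path)):
        return read_features(annotation)
    return list(annotation)
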