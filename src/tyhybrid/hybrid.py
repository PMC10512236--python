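"""Hard-masked parental genomes and concatenated hybrid references.

The mapping strategy collapses all genomic copies of a Ty family onto one
pseudo-chromosome: every annotated Ty interval (full-length parts and solo
LTRs alike) is replaced by Ns in the chromosomal sequence, and a single
representative sequence per family is appended as an extra contig. Three
dataset dialects differ in what that pseudo-chromosome contains:

* ``three_prime`` — internal sequence concatenated with its 3' LTR, so
  3'-end read pairs anchored in the internal sequence may extend into the
  LTR;
* ``separate`` — internal and LTR sequences as distinct entries;
* ``five_prime`` — 5' LTR followed by the complete internal sequence
  (ribosome-profiling layout, capturing starts near the LTR/internal
  boundary).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from tyhybrid.annotations import Feature, make_feature, write_features
from tyhybrid.reference import TyFamilyReference

DIALECTS = ("three_prime", "separate", "five_prime")


@dataclasses.dataclass(frozen=True)
class MaskSpec:
    """Per-contig intervals (0-based half-open) to replace with N.

    Overlapping intervals are allowed; their union is masked.
    """

    intervals: Mapping[str, Sequence[tuple]]

    @classmethod
    def from_te_annotations(cls, records) -> "MaskSpec":
        by_contig: dict[str, list[tuple]] = {}
        for r in records:
            by_contig.setdefault(r.contig, []).append((r.start, r.end))
        return cls({c: sorted(v) for c, v in by_contig.items()})


@dataclasses.dataclass
class HybridReference:
    """Masked concatenated contigs plus single-copy Ty pseudo-chromosomes."""

    contigs: dict[str, str]
    provenance: dict[str, str]  # contig -> parent1 | parent2 | ty_pseudo
    features: list[Feature]
    dialect: str

    @property
    def pseudo_chromosomes(self) -> list[str]:
        return [c for c, p in self.provenance.items() if p == "ty_pseudo"]

    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}


def hard_mask(assembly: Mapping[str, str], mask: MaskSpec) -> dict[str, str]:
    """Replace masked intervals with N; lengths and other bases unchanged."""
    out = {}
    for contig, seq in assembly.items():
        intervals = mask.intervals.get(contig, ())
        if not intervals:
            out[contig] = seq
            continue
        chars = list(seq)
        for start, end in intervals:
            if not (0 <= start < end <= len(seq)):
                raise ValueError(
                    f"mask interval [{start}, {end}) outside contig "
                    f"{contig!r} of length {len(seq)}"
                )
            chars[start:end] = "N" * (end - start)
        out[contig] = "".join(chars)
    return out


def _pseudo_entries(ref: TyFamilyReference, dialect: str):
    """Yield (contig_name, sequence, features) for one family's entry."""
    name = ref.family_name
    if dialect == "three_prime":
        seq = ref.internal_seq + ref.ltr3_seq
        feats = [
            make_feature(name, 0, len(ref.internal_seq), "+", "transcript",
                         transcript_id=name, family=name, part="internal"),
            make_feature(name, len(ref.internal_seq), len(seq), "+",
                         "long_terminal_repeat",
                         transcript_id=f"{name}_LTR3", family=name, part="LTR"),
        ]
        yield name, seq, feats
    elif dialect == "five_prime":
        seq = ref.ltr5_seq + ref.internal_seq
        off = len(ref.ltr5_seq)
        feats = [
            make_feature(name, 0, off, "+", "long_terminal_repeat",
                         transcript_id=f"{name}_LTR5", family=name, part="LTR"),
            make_feature(name, off, len(seq), "+", "transcript",
                         transcript_id=name, family=name, part="internal"),
        ]
        if ref.gag is not None or ref.pol is not None:
            # ORF coordinates transfer directly: the five_prime layout is the
            # full-element layout minus the 3' LTR.
            for label, orf in (("GAG", ref.gag), ("POL", ref.pol)):
                if orf is not None:
                    feats.append(
                        make_feature(name, orf.start, orf.end, "+", "CDS",
                                     transcript_id=f"{name}_{label}",
                                     family=name, orf=label)
                    )
        yield name, seq, feats
    elif dialect == "separate":
        yield (
            f"{name}_I",
            ref.internal_seq,
            [make_feature(f"{name}_I", 0, len(ref.internal_seq), "+", "transcript",
                          transcript_id=name, family=name, part="internal")],
        )
        yield (
            f"{name}_LTR",
            ref.ltr3_seq,
            [make_feature(f"{name}_LTR", 0, len(ref.ltr3_seq), "+", "transcript",
                          transcript_id=f"{name}_LTR", family=name, part="LTR")],
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def build_hybrid_reference(
    masked_parent1: Mapping[str, str],
    masked_parent2: Mapping[str, str] | None,
    ty_library: Sequence[TyFamilyReference],
    dialect: str,
    parent1_features: Sequence[Feature] = (),
    parent2_features: Sequence[Feature] = (),
    parent_tags: tuple = ("p1", "p2"),
) -> HybridReference:
    """Concatenate masked parents and append Ty pseudo-chromosomes.

    Contig names are prefixed with the parent tag to guarantee uniqueness.
    ``masked_parent2`` may be None for a parent-only build. Gene features
    from each parent are relabelled onto the prefixed contigs.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    names = [r.family_name for r in ty_library]
    if len(set(names)) != len(names):
        raise ValueError(
            "duplicate family names in Ty library; suffix families with their "
            f"host species: {sorted(n for n in names if names.count(n) > 1)}"
        )

    contigs: dict[str, str] = {}
    provenance: dict[str, str] = {}
    features: list[Feature] = []

    parents = [("parent1", parent_tags[0], masked_parent1, parent1_features)]
    if masked_parent2 is not None:
        parents.append(("parent2", parent_tags[1], masked_parent2, parent2_features))

    for label, tag, assembly, feats in parents:
        for contig, seq in assembly.items():
            new_name = f"{tag}_{contig}"
            contigs[new_name] = seq
            provenance[new_name] = label
        for f in feats:
            features.append(
                dataclasses.replace(
                    f, contig=f"{tag}_{f.contig}",
                    attrs=tuple(sorted(dict(f.attrs, subgenome=label).items())),
                )
            )

    for ref in ty_library:
        for name, seq, feats in _pseudo_entries(ref, dialect):
            if name in contigs:
                raise ValueError(f"pseudo-chromosome name collision: {name!r}")
            contigs[name] = seq
            provenance[name] = "ty_pseudo"
            features.extend(feats)

    return HybridReference(contigs, provenance, features, dialect)


def emit_annotation(ref: HybridReference, path, fmt: str = "gtf") -> None:
    """Write the reference's features as GTF/GFF3 with transcript_id attrs."""
    feats = []
    for f in ref.features:
        if f.attr("transcript_id") is None:
            f = f.with_attrs(transcript_id=f"{f.contig}:{f.start}-{f.end}")
        feats.append(f)
    write_features(feats, path, fmt=fmt)


def write_reference(ref: HybridReference, out_dir, fmt: str = "gtf") -> None:
    from pathlib import Path

    from tyhybrid.annotations import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ref.contigs, out / "hybrid_genome.fasta")
    ext = "gtf" if fmt == "gtf" else "gff3"
    emit_annotation(ref, out / f"hybrid_annotation.{ext}", fmt=fmt)
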