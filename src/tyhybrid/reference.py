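"""Representative Ty family reference sequences and ORF annotation.

A Ty family reference is built in three steps: extract all annotated copies
of a family part (internal or LTR) from the assembly, derive a
majority-rule consensus from a multiple alignment of those copies, then
pick the single annotated copy most similar to the consensus as the
representative. The representative full-length layout
(5' LTR + internal + 3' LTR) is scanned for the two overlapping ORFs, GAG
and POL: in canonical full-length elements the GAG start codon lies 40 bp
upstream of the 5' LTR end and the POL stop codon 25 bp upstream of the
3' LTR start, with POL translated in a different frame via a programmed
frameshift inside GAG.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from tyhybrid.annotations import TeAnnotationRecord, revcomp

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Minimum ORF length (nt, incl. stop) considered a real coding region.
MIN_ORF_LEN = 300

#: GAG candidate starts must lie within this distance of the 5' LTR end.
GAG_START_WINDOW = 100


@dataclasses.dataclass(frozen=True)
class ConsensusResult:
    """Majority-rule consensus over an alignment.

    ``sequence`` is over {A,C,G,T,N}: a column is called only when a unique
    most frequent non-gap base reaches the frequency threshold; ties and
    sub-threshold columns are N. Columns gapped in every sequence are
    dropped, so ``len(sequence)`` equals the number of retained columns.
    """

    sequence: str
    column_frequencies: tuple
    n_input: int


@dataclasses.dataclass(frozen=True)
class OrfInterval:
    """Half-open interval of an ORF on the full-element layout, with frame."""

    start: int
    end: int

    @property
    def frame(self) -> int:
        return self.start % 3

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class TyFamilyReference:
    """A family's representative sequences plus ORF structure.

    ``family_name`` carries the host-species suffix (e.g. ``Ty1_cer``) so
    orthologous families from the two parents stay distinct. ``gag`` may be
    None for families lacking an annotated GAG (the Ty5_par case).
    """

    family_name: str
    internal_seq: str
    ltr5_seq: str
    ltr3_seq: str
    gag: OrfInterval | None = None
    pol: OrfInterval | None = None

    @property
    def full_sequence(self) -> str:
        return self.ltr5_seq + self.internal_seq + self.ltr3_seq

    @property
    def frameshift_overlap(self) -> OrfInterval | None:
        """Interval where GAG and POL overlap in different frames."""
        if self.gag is None or self.pol is None:
            return None
        lo, hi = max(self.gag.start, self.pol.start), min(self.gag.end, self.pol.end)
        if lo >= hi or self.gag.frame == self.pol.frame:
            return None
        return OrfInterval(lo, hi)

    def to_dict(self) -> dict:
        def orf(o):
            return None if o is None else [o.start, o.end]

        return {
            "family_name": self.family_name,
            "ltr5_len": len(self.ltr5_seq),
            "internal_len": len(self.internal_seq),
            "ltr3_len": len(self.ltr3_seq),
            "gag": orf(self.gag),
            "pol": orf(self.pol),
        }


# ---------------------------------------------------------------------------
# Sequence extraction


def extract_te_sequences(
    assembly: Mapping[str, str],
    annotations: Sequence[TeAnnotationRecord],
    family: str,
    part: str,
) -> list[str]:
    """Extract oriented sequences of one family part from an assembly.

    Minus-strand records are reverse-complemented. Output order is
    deterministic: sorted by (contig, start). An empty result is an empty
    list, not an error.
    """
    selected = sorted(
        (r for r in annotations if r.family == family and r.part == part),
        key=lambda r: (r.contig, r.start),
    )
    out = []
    for rec in selected:
        if rec.contig not in assembly:
            raise KeyError(f"unknown contig {rec.contig!r} in TE annotation")
        contig_seq = assembly[rec.contig]
        if rec.end > len(contig_seq):
            raise ValueError(
                f"record [{rec.start}, {rec.end}) exceeds contig "
                f"{rec.contig!r} length {len(contig_seq)}"
            )
        seq = contig_seq[rec.start:rec.end]
        out.append(revcomp(seq) if rec.strand == "-" else seq)
    return out


# ---------------------------------------------------------------------------
# Consensus


def build_consensus(aligned_seqs: Sequence[str], threshold: float = 0.5) -> ConsensusResult:
    """Majority-rule consensus of equal-length gapped sequences.

    Per column, the consensus base is the unique most frequent non-gap
    character whose frequency among non-gap characters is >= ``threshold``;
    a tie for the top frequency is ambiguous (N) even at exactly the
    threshold. Columns gapped in all sequences are dropped.
    """
    if len(aligned_seqs) < 2:
        raise ValueError("consensus requires at least 2 sequences")
    lengths = {len(s) for s in aligned_seqs}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")

    chars = []
    freqs = []
    for col in zip(*(s.upper() for s in aligned_seqs)):
        counts = Counter(c for c in col if c not in GAP_CHARS)
        if not counts:  # all-gap column: dropped
            continue
        total = sum(counts.values())
        ranked = counts.most_common()
        best_char, best_n = ranked[0]
        tie = len(ranked) > 1 and ranked[1][1] == best_n
        freq = best_n / total
        if tie or freq < threshold:
            chars.append("N")
        else:
            chars.append(best_char)
        freqs.append({c: n / total for c, n in counts.items()})
    return ConsensusResult("".join(chars), tuple(freqs), len(aligned_seqs))


# ---------------------------------------------------------------------------
# Representative selection

#: BLASTN-like local alignment scoring; only the argmax over candidates
#: matters. N pairs score as mismatches.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2.0, -3.0, -5.0, -2.0


def _local_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                m[a, b] = MATCH
            else:
                m[a, b] = MISMATCH
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = m
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def local_alignment_score(a: str, b: str) -> float:
    """Smith-Waterman score with the module's scoring scheme."""
    return _local_aligner().score(a.upper(), b.upper())


def select_representative(
    consensus: ConsensusResult | str,
    candidates: Sequence[str],
) -> int:
    """Index of the candidate with the highest local-alignment score.

    Ties are broken by candidate order, which callers provide sorted by
    genomic position (contig, start).
    """
    if len(candidates) == 0:
        raise ValueError("no candidate sequences to choose from")
    cseq = consensus.sequence if isinstance(consensus, ConsensusResult) else consensus
    aligner = _local_aligner()
    scores = [aligner.score(cseq.upper(), cand.upper()) for cand in candidates]
    return int(np.argmax(scores))


# ---------------------------------------------------------------------------
# ORF annotation


def _find_orfs(seq: str, min_len: int = MIN_ORF_LEN) -> list[OrfInterval]:
    """All forward-strand ORFs (ATG..stop, stop included) of >= min_len."""
    seq = seq.upper()
    n = len(seq)
    orfs = []
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                if pos + 3 - start >= min_len:
                    orfs.append(OrfInterval(start, pos + 3))
                start = None
    return orfs


def annotate_orfs(ref: TyFamilyReference, min_len: int = MIN_ORF_LEN) -> TyFamilyReference:
    """Annotate GAG/POL on a full-length layout (5'LTR + internal + 3'LTR).

    GAG is the longest ORF starting within :data:`GAG_START_WINDOW` bp of
    the 5' LTR end; POL is the longest ORF in a different frame that
    overlaps GAG's 3' portion and ends upstream of the 3' LTR. Absence of a
    qualifying GAG is recorded as None (some families, e.g. Ty5 of
    S. paradoxus, carry no separate GAG), not raised.
    """
    seq = ref.full_sequence
    ltr5_end = len(ref.ltr5_seq)
    ltr3_start = ltr5_end + len(ref.internal_seq)

    orfs = _find_orfs(seq, min_len=min_len)
    if not orfs:
        warnings.warn(
            f"{ref.family_name}: no ORF >= {min_len} bp found; leaving ORFs unannotated",
            stacklevel=2,
        )
        return dataclasses.replace(ref, gag=None, pol=None)

    gag_candidates = [o for o in orfs if abs(o.start - ltr5_end) <= GAG_START_WINDOW]
    gag = max(gag_candidates, key=lambda o: o.length, default=None)

    pol_candidates = [o for o in orfs if o.end <= ltr3_start]
    if gag is not None:
        pol_candidates = [
            o
            for o in pol_candidates
            if o.frame != gag.frame and o.start < gag.end and o.end > gag.end
        ]
    else:
        pol_candidates = [o for o in pol_candidates if o is not gag]
    pol = max(pol_candidates, key=lambda o: o.length, default=None)

    return dataclasses.replace(ref, gag=gag, pol=pol)


# ---------------------------------------------------------------------------
# Family reference assembly


def build_family_reference(
    assembly: Mapping[str, str],
    annotations: Sequence[TeAnnotationRecord],
    family: str,
    species_tag: str,
    aligner=None,
    threshold: float = 0.5,
) -> TyFamilyReference:
    """Build one family's reference from annotated full-length copies.

    Only full-length elements (an internal record flanked by two LTR
    records sharing its element_id) contribute to the consensus. With a
    single full-length copy the consensus step is skipped and that copy is
    the representative. ``aligner`` is a callable mapping a list of
    sequences to a list of equal-length gapped sequences; it is only needed
    when more than one copy exists.
    """
    by_element: dict[str, dict[str, list[TeAnnotationRecord]]] = {}
    for rec in annotations:
        if rec.family != family:
            continue
        by_element.setdefault(rec.element_id, {}).setdefault(rec.part, []).append(rec)

    full_length = {
        eid: parts
        for eid, parts in by_element.items()
        if len(parts.get("internal", [])) == 1 and len(parts.get("LTR", [])) == 2
    }
    if not full_length:
        raise ValueError(f"no full-length {family} element in annotations")

    elements = []
    for eid in sorted(full_length, key=lambda e: _element_sort_key(full_length[e])):
        parts = full_length[eid]
        internal = parts["internal"][0]
        ltrs = sorted(parts["LTR"], key=lambda r: r.start)
        # 5' LTR precedes the internal sequence in element orientation
        if internal.strand == "+":
            ltr5, ltr3 = ltrs[0], ltrs[1]
        else:
            ltr5, ltr3 = ltrs[1], ltrs[0]
        elements.append((internal, ltr5, ltr3))

    def part_seq(rec: TeAnnotationRecord) -> str:
        seq = assembly[rec.contig][rec.start:rec.end]
        return revcomp(seq) if rec.strand == "-" else seq

    internals = [part_seq(i) for i, _, _ in elements]
    if len(elements) == 1:
        idx = 0
    else:
        if aligner is None:
            from tyhybrid.msa import progressive_align

            aligner = progressive_align
        consensus = build_consensus(aligner(internals), threshold=threshold)
        idx = select_representative(consensus, internals)

    internal, ltr5, ltr3 = elements[idx]
    ref = TyFamilyReference(
        family_name=f"{family}_{species_tag}",
        internal_seq=internals[idx],
        ltr5_seq=part_seq(ltr5),
        ltr3_seq=part_seq(ltr3),
    )
    return annotate_orfs(ref)


def _element_sort_key(parts):
    rec = parts["internal"][0]
    return (rec.contig, rec.start)


# ---------------------------------------------------------------------------
# Library serialization


def write_ty_library(refs: Sequence[TyFamilyReference], out_dir) -> None:
    """Write the Ty library as multi-FASTA plus a JSON ORF sidecar."""
    from pathlib import Path

    from tyhybrid.annotations import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = {}
    meta = {}
    for ref in refs:
        seqs[f"{ref.family_name}_internal"] = ref.internal_seq
        seqs[f"{ref.family_name}_LTR5"] = ref.ltr5_seq
        seqs[f"{ref.family_name}_LTR3"] = ref.ltr3_seq
        meta[ref.family_name] = ref.to_dict()
    write_fasta(seqs, out / "ty_library.fasta")
    with open(out / "ty_library.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_ty_library(out_dir) -> list[TyFamilyReference]:
    from pathlib import Path

    from tyhybrid.annotations import read_fasta

    out = Path(out_dir)
    seqs = read_fasta(out / "ty_library.fasta")
    with open(out / "ty_library.json") as fh:
        meta = json.load(fh)
    refs = []
    for name, info in meta.items():
        def orf(v):
            return None if v is None else OrfInterval(v[0], v[1])

        refs.append(
            TyFamilyReference(
                family_name=name,
                internal_seq=seqs[f"{name}_internal"],
                ltr5_seq=seqs[f"{name}_LTR5"],
                ltr3_seq=seqs[f"{name}_LTR3"],
                gag=orf(info["gag"]),
                pol=orf(info["pol"]),
            )
        )
    return refs
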