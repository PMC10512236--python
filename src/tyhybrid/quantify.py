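"""Alignment filtering, family/gene-level counting, TPM and coverage.

Counting is fragment-level (a properly paired read pair is one fragment)
against non-overlapping transcript features, with options mirroring the
pipeline's counting conventions: reverse-stranded mode (the second-in-pair
mate matches the transcript strand), a minimum fragment length of 5, and
multi-overlap handling that is either drop (count nothing) or fractional
(1/n to each of the n features hit).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from tyhybrid.annotations import Feature

logger = logging.getLogger(__name__)

DEFAULT_MIN_FRAGMENT = 5
COVERAGE_WINDOW = 75


def _open_alignments(alignments):
    """Accept a pysam AlignmentFile, a path, or an iterable of segments."""
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments)) as fh:
            yield from fh
    else:
        yield from alignments


# ---------------------------------------------------------------------------
# Read filters


def filter_polyT_pairs(read_pairs: Iterable) -> list:
    """Keep pairs where at least one mate's first two bases are both T.

    ``read_pairs`` yields ``(name, seq1, seq2)`` tuples (sequences in
    sequencing orientation, as in FASTQ). Reads lacking a mate indicate
    broken pairing upstream and raise.
    """
    kept = []
    for rec in read_pairs:
        try:
            name, seq1, seq2 = rec
        except (TypeError, ValueError) as exc:
            raise ValueError(f"orphan or malformed read pair record: {rec!r}") from exc
        if seq1 is None or seq2 is None:
            raise ValueError(f"orphan read in pair {name!r}")
        if seq1[:2].upper() == "TT" or seq2[:2].upper() == "TT":
            kept.append(rec)
    return kept


def read_fastq_pairs(path1, path2):
    """Iterate (name, seq1, seq2) from a pair of FASTQ files."""
    def seqs(path):
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    return
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                yield header[1:].split()[0], seq

    for (n1, s1), (n2, s2) in zip(seqs(path1), seqs(path2)):
        if n1 != n2:
            raise ValueError(f"read pairing broken: {n1!r} vs {n2!r}")
        yield n1, s1, s2


def drop_secondary(alignments) -> list:
    """Remove records with the secondary-alignment flag (0x100) set."""
    out = [a for a in _open_alignments(alignments) if not a.is_secondary]
    return out


def _pairs_by_name(records) -> dict:
    pairs: dict = {}
    for a in records:
        pairs.setdefault(a.query_name, []).append(a)
    return pairs


def select_internal_pairs(
    alignments,
    ty_annotation: Sequence[Feature],
    dialect: str = "three_prime",
) -> list:
    """Keep Ty-assignable pairs under the 3'-end dialect's rules.

    A pair on a Ty pseudo-chromosome is kept only when it is paired,
    properly paired, and its first-in-pair mate starts inside the internal
    interval (mates extending into the 3' LTR are accepted). Pairs lying
    wholly within LTR-only features are thereby excluded — the point of
    the rule is to reject spurious transcription from solo LTRs. Pairs on
    non-Ty contigs pass through unchanged.
    """
    if dialect != "three_prime":
        raise ValueError(
            f"internal-pair selection applies to the three_prime dialect, "
            f"not {dialect!r}"
        )
    internal: dict = {}
    ty_contigs = set()
    for f in ty_annotation:
        ty_contigs.add(f.contig)
        if f.attr("part") == "internal" or f.kind == "transcript":
            internal.setdefault(f.contig, []).append((f.start, f.end))

    records = list(_open_alignments(alignments))
    if any(not a.is_paired for a in records):
        raise ValueError("pair selection rules requested on single-end data")
    out = []
    by_name = _pairs_by_name(records)
    for name, recs in by_name.items():
        on_ty = [a for a in recs if a.reference_name in ty_contigs]
        if not on_ty:
            out.extend(recs)
            continue
        first = [a for a in recs if a.is_paired and a.is_proper_pair and a.is_read1
                 and not a.is_unmapped]
        keep = False
        for a in first:
            for s, e in internal.get(a.reference_name, ()):
                if s <= a.reference_start < e:
                    keep = True
        if keep:
            out.extend(recs)
    n_dropped = len(records) - len(out)
    if n_dropped:
        logger.info("select_internal_pairs: dropped %d records", n_dropped)
    return out


# ---------------------------------------------------------------------------
# Counting


@dataclasses.dataclass
class CountOptions:
    stranded: str = "none"          # none | reverse
    multimap: str = "drop"          # drop | fractional
    min_fragment: int = DEFAULT_MIN_FRAGMENT


def _fragments(records):
    """Group alignments into fragments: (contig, start, end, strand2, length).

    For pairs, the fragment spans both mates, its length is the template
    length and its orientation is that of the second-in-pair mate (the
    mate matching the transcript strand under the reverse-stranded
    convention). Single-end reads are their own fragments.
    """
    by_name = _pairs_by_name(a for a in records if not a.is_unmapped)
    for name, recs in by_name.items():
        primaries = [a for a in recs if not a.is_secondary]
        if not primaries:
            continue
        if primaries[0].is_paired:
            mates = {a.is_read1: a for a in primaries}
            r1, r2 = mates.get(True), mates.get(False)
            if r1 is None or r2 is None:
                continue
            start = min(r1.reference_start, r2.reference_start)
            end = max(r1.reference_end, r2.reference_end)
            strand = "-" if r2.is_reverse else "+"
            length = abs(r1.template_length) or (end - start)
            yield name, r1.reference_name, start, end, strand, length
        else:
            for a in primaries:
                strand = "-" if a.is_reverse else "+"
                yield (name, a.reference_name, a.reference_start,
                       a.reference_end, strand, a.query_length)


def count_features(
    alignments,
    annotation: Sequence[Feature],
    options: CountOptions | None = None,
) -> pd.Series:
    """Fragment counts per transcript feature.

    Overlap means >= 1 base of the fragment within the feature. In
    reverse-stranded mode, fragments whose sense mate orientation differs
    from the feature strand are not assigned. Under fractional mode a
    fragment overlapping n features contributes 1/n to each; under drop
    mode it contributes nothing when n > 1.
    """
    options = options or CountOptions()
    feats = [f for f in annotation if f.attr("transcript_id") is not None]
    ids = [f.attr("transcript_id") for f in feats]
    by_contig: dict = {}
    for f in feats:
        by_contig.setdefault(f.contig, []).append(f)

    counts = pd.Series(0.0, index=pd.Index(ids, name="feature"))
    n_unassigned = 0
    for name, contig, start, end, strand, length in _fragments(
        _open_alignments(alignments)
    ):
        if length < options.min_fragment:
            continue
        hits = []
        for f in by_contig.get(contig, ()):
            if not f.overlaps(start, end):
                continue
            if options.stranded == "reverse" and f.strand != strand:
                continue
            hits.append(f.attr("transcript_id"))
        if not hits:
            n_unassigned += 1
            continue
        if len(hits) == 1:
            counts[hits[0]] += 1.0
        elif options.multimap == "fractional":
            w = 1.0 / len(hits)
            for h in hits:
                counts[h] += w
        # drop mode: ambiguous fragments count nothing
    if n_unassigned:
        logger.info("count_features: %d fragments overlapped no feature",
                    n_unassigned)
    return counts


def build_count_matrix(sam_paths: dict, annotation: Sequence[Feature],
                       options: CountOptions | None = None) -> pd.DataFrame:
    """Counts for several samples: features x samples DataFrame."""
    cols = {}
    for sample, path in sam_paths.items():
        cols[sample] = count_features(path, annotation, options)
    return pd.DataFrame(cols)


def feature_lengths(annotation: Sequence[Feature]) -> pd.Series:
    feats = [f for f in annotation if f.attr("transcript_id") is not None]
    return pd.Series(
        {f.attr("transcript_id"): f.length for f in feats}, name="length"
    )


# ---------------------------------------------------------------------------
# TPM


def compute_tpm(counts, lengths) -> pd.DataFrame:
    """Transcripts per million: 1e6 * (c_i/L_i) / sum_j (c_j/L_j).

    ``counts`` may be a Series (one sample) or DataFrame (features x
    samples); ``lengths`` a Series aligned on features. All-zero samples
    yield all-zero TPM.
    """
    frame = counts.to_frame() if isinstance(counts, pd.Series) else counts
    lengths = lengths.reindex(frame.index)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")
    rate = frame.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        logger.info("compute_tpm: all-zero sample(s): %s",
                    list(frame.columns[zero]))
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    return tpm[counts.name] if isinstance(counts, pd.Series) else tpm


# ---------------------------------------------------------------------------
# Coverage profiles


@dataclasses.dataclass
class CoverageProfile:
    reference: str
    depth: np.ndarray          # per-base depth
    window: int
    window_means: np.ndarray
    zscores: np.ndarray


def per_base_depth(alignments, reference: str, length: int) -> np.ndarray:
    """Depth from primary alignments; zero-depth positions included."""
    depth = np.zeros(length, dtype=float)
    for a in _open_alignments(alignments):
        if a.is_secondary or a.is_unmapped or a.reference_name != reference:
            continue
        s = max(0, a.reference_start)
        e = min(length, a.reference_end)
        if e > s:
            depth[s:e] += 1
    return depth


def coverage_zscores(alignments, reference: str, length: int,
                     window: int = COVERAGE_WINDOW) -> CoverageProfile:
    """Windowed z-scores of mean coverage depth.

    Depth is averaged in non-overlapping windows (the trailing partial
    window is dropped) and standardized across windows. Zero variance
    across windows yields all-zero z-scores.
    """
    if length < window:
        raise ValueError(
            f"reference length {length} shorter than window {window}"
        )
    depth = per_base_depth(alignments, reference, length)
    n_win = length // window
    means = depth[: n_win * window].reshape(n_win, window).mean(axis=1)
    sd = means.std(ddof=0)
    if sd == 0:
        logger.info("coverage_zscores: zero variance on %s", reference)
        z = np.zeros_like(means)
    else:
        z = (means - means.mean()) / sd
    return CoverageProfile(reference, depth, window, means, z)
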