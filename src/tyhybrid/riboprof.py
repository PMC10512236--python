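"""Ribosome profiling: P-site offsets, region-restricted CDS counting and
translation efficiency.

A ribosome-protected fragment (RPF) covers the ribosome's P-site at a
fixed distance from its 5' end that depends on fragment length. Offsets
are estimated per read length from the metagene of 5' ends around
annotated start codons; the 3-nt periodicity of offset-corrected 5' ends
(phasing) is reported per length. Reads outside the 27-32 nt range are
discarded. Counting assigns each RPF to its P-site position and each
total-mRNA read to its central position, restricted to a region mode:
the full CDS, the first 60 coding nucleotides (a proxy for translation
initiation), or the POL-specific portion of a Ty family (from the GAG
stop to the POL stop). Translation efficiency is the RPF/mRNA ratio,
tested as the species:experiment interaction of a two-factor NB model;
a positive interaction log2 fold change means higher translation
efficiency in the hybrid.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tyhybrid.annotations import Feature
from tyhybrid.detest import DesignSpec, nb_wald_fit, size_factors
from tyhybrid.quantify import _open_alignments

logger = logging.getLogger(__name__)

RPF_LENGTH_RANGE = (27, 32)
DEFAULT_PADDING = 50
#: Metagene window around the start codon for the offset search:
#: 5' ends within [start - 40, start + 20].
METAGENE_UP, METAGENE_DOWN = 40, 20


# ---------------------------------------------------------------------------
# Annotation padding


def pad_annotations(annotation: Sequence[Feature],
                    pad: int = DEFAULT_PADDING) -> list:
    """Extend each CDS ``pad`` nt upstream (clamped at 0) to simulate
    5' UTRs; the original CDS start is kept in the ``cds_start`` attr."""
    out = []
    for f in annotation:
        if f.kind != "CDS":
            out.append(f)
            continue
        if f.strand == "+":
            new_start = max(0, f.start - pad)
            out.append(
                dataclasses.replace(f, start=new_start).with_attrs(
                    cds_start=f.start, cds_end=f.end
                )
            )
        else:
            out.append(
                f.with_attrs(cds_start=f.start, cds_end=f.end)
            )  # minus-strand padding would extend end; not used here
    return out


def _cds_start(f: Feature) -> int:
    v = f.attr("cds_start")
    return f.start if v is None else int(v)


def _cds_end(f: Feature) -> int:
    v = f.attr("cds_end")
    return f.end if v is None else int(v)


# ---------------------------------------------------------------------------
# P-site offsets


@dataclasses.dataclass
class PsiteOffsets:
    offsets: dict            # read length -> 5' offset (nt)
    phasing: dict            # read length -> dominant-frame fraction
    accepted_lengths: tuple  # lengths within RPF_LENGTH_RANGE with data

    def offset(self, length: int) -> int:
        return self.offsets[length]


def _five_prime_end(a) -> int:
    return a.reference_end - 1 if a.is_reverse else a.reference_start


def estimate_psite_offsets(
    rpf_alignments,
    annotation: Sequence[Feature],
    length_range: tuple = RPF_LENGTH_RANGE,
) -> PsiteOffsets:
    """Per-length P-site offsets from the start-codon metagene.

    For each read length L, the offset is the argmax over d in [0, L) of
    the histogram of (start codon position - read 5' end), restricted to
    5' ends within [start - METAGENE_UP, start + METAGENE_DOWN]. The
    phasing fraction per length is the dominant-frame share of
    offset-corrected 5' ends falling inside CDS intervals.
    """
    lo, hi = length_range
    cds = [f for f in annotation if f.kind == "CDS"]
    if not cds:
        raise ValueError("no CDS features in annotation")
    starts_by_contig: dict = {}
    intervals_by_contig: dict = {}
    for f in cds:
        starts_by_contig.setdefault(f.contig, []).append(_cds_start(f))
        intervals_by_contig.setdefault(f.contig, []).append(
            (_cds_start(f), _cds_end(f))
        )
    for v in starts_by_contig.values():
        v.sort()

    hist: dict = {L: np.zeros(L, dtype=int) for L in range(lo, hi + 1)}
    reads: dict = {L: [] for L in range(lo, hi + 1)}
    n_metagene = 0
    for a in _open_alignments(rpf_alignments):
        if a.is_unmapped or a.is_secondary:
            continue
        L = a.query_length
        if L < lo or L > hi:
            continue
        e = _five_prime_end(a)
        reads[L].append((a.reference_name, e))
        for s in starts_by_contig.get(a.reference_name, ()):
            d = s - e
            if -METAGENE_DOWN <= d <= METAGENE_UP and 0 <= d < L:
                hist[L][d] += 1
                n_metagene += 1
    if n_metagene == 0:
        raise ValueError("no reads near any annotated start codon")

    offsets: dict = {}
    phasing: dict = {}
    for L in range(lo, hi + 1):
        if hist[L].sum() == 0:
            continue
        offsets[L] = int(np.argmax(hist[L]))
        frames = np.zeros(3, dtype=int)
        for contig, e in reads[L]:
            p = e + offsets[L]
            hits = [
                (s, t) for s, t in intervals_by_contig.get(contig, ())
                if s <= p < t
            ]
            # positions inside overlapping ORFs (the GAG/POL frameshift
            # region) have no unique frame and are skipped
            if len(hits) == 1:
                s, _ = hits[0]
                frames[(p - s) % 3] += 1
        phasing[L] = float(frames.max() / frames.sum()) if frames.sum() else np.nan
    return PsiteOffsets(offsets, phasing, tuple(sorted(offsets)))


# ---------------------------------------------------------------------------
# Region-restricted counting


@dataclasses.dataclass
class CdsRegionSpec:
    mode: str = "full"            # full | first60 | pol_only
    first_n: int = 60


def _counting_intervals(annotation: Sequence[Feature],
                        region: CdsRegionSpec) -> dict:
    """feature id -> (contig, start, end) counted interval.

    Gene CDS features count under their transcript_id. Ty families carry
    GAG/POL CDS sub-features (attr ``orf``); the family counts as one
    feature whose full interval spans from the first ORF start to the POL
    stop, and whose pol_only interval runs from the GAG stop to the POL
    stop (families without POL are skipped in pol_only mode).
    """
    genes: dict = {}
    ty_orfs: dict = {}
    for f in annotation:
        if f.kind != "CDS":
            continue
        orf = f.attr("orf")
        if orf is None:
            tid = f.attr("transcript_id")
            if tid is not None:
                genes[tid] = (f.contig, _cds_start(f), _cds_end(f))
        else:
            family = f.attr("family")
            ty_orfs.setdefault(family, {})[orf] = (
                f.contig, _cds_start(f), _cds_end(f)
            )

    out: dict = {}
    for tid, (contig, s, e) in genes.items():
        if region.mode == "first60":
            out[tid] = (contig, s, min(e, s + region.first_n))
        elif region.mode == "pol_only":
            continue  # host genes have no POL; Ty-only mode
        else:
            out[tid] = (contig, s, e)
    for family, orfs in ty_orfs.items():
        pol = orfs.get("POL")
        gag = orfs.get("GAG")
        if region.mode == "pol_only":
            if pol is None:
                logger.info("pol_only: %s lacks POL annotation; skipped", family)
                continue
            start = gag[2] if gag is not None else pol[1]
            out[family] = (pol[0], start, pol[2])
        else:
            first = gag if gag is not None else pol
            if first is None:
                continue
            s = first[1]
            e = pol[2] if pol is not None else first[2]
            if region.mode == "first60":
                e = min(e, s + region.first_n)
            out[family] = (first[0], s, e)
    return out


def count_cds(
    alignments,
    annotation: Sequence[Feature],
    offsets: PsiteOffsets | None = None,
    region: CdsRegionSpec | str = "full",
    library: str = "rpf",
) -> pd.Series:
    """Positional counts per feature.

    RPF reads are assigned to (5' end + per-length offset) and counted if
    that P-site position falls inside the feature's counted interval;
    total-mRNA reads are assigned to their central position. RPF reads
    with lengths lacking an offset are discarded.
    """
    if isinstance(region, str):
        region = CdsRegionSpec(mode=region)
    if library == "rpf" and offsets is None:
        raise ValueError("P-site offsets are required for RPF counting")
    intervals = _counting_intervals(annotation, region)
    by_contig: dict = {}
    for fid, (contig, s, e) in intervals.items():
        by_contig.setdefault(contig, []).append((s, e, fid))

    counts = pd.Series(0.0, index=pd.Index(sorted(intervals), name="feature"))
    for a in _open_alignments(alignments):
        if a.is_unmapped or a.is_secondary:
            continue
        if library == "rpf":
            L = a.query_length
            if L not in offsets.offsets:
                continue
            pos = _five_prime_end(a) + offsets.offsets[L]
        else:
            pos = (a.reference_start + a.reference_end - 1) // 2
        for s, e, fid in by_contig.get(a.reference_name, ()):
            if s <= pos < e:
                counts[fid] += 1.0
                break
    return counts


# ---------------------------------------------------------------------------
# Translation efficiency


def translation_efficiency(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    focal_parent: str,
    hybrid_level: str = "hybrid",
    species_column: str = "species",
    assay_column: str = "experiment",
    mrna_level: str = "mrna",
    dispersion=None,
    shrink: bool = False,
) -> pd.DataFrame:
    """Interaction-model test of translation efficiency, per subgenome.

    ``counts`` holds matched RPF and mRNA samples as columns;
    ``sample_sheet`` marks each sample's species and experiment (mrna or
    rpf). The model counts ~ species + experiment + species:experiment is
    fitted with the parent and mRNA as reference levels; the interaction
    coefficient is the log2 translation-efficiency change in the hybrid.
    An optional normal-prior ridge shrinks the interaction estimate toward
    zero using the empirical spread of unshrunk estimates (off by
    default).
    """
    sheet = sample_sheet.loc[counts.columns]
    keep = sheet[species_column].isin([focal_parent, hybrid_level])
    sheet = sheet[keep]
    sub = counts[sheet.index]

    assay_levels = sorted(sheet[assay_column].astype(str).unique())
    other = [l for l in assay_levels if l != mrna_level]
    if len(other) != 1:
        raise ValueError(f"expected two assay levels, got {assay_levels}")
    contrast = (
        f"{species_column}_{hybrid_level}_vs_{focal_parent}"
        f":{assay_column}_{other[0]}_vs_{mrna_level}"
    )
    spec = DesignSpec(
        terms=[species_column, assay_column, (species_column, assay_column)],
        contrast=contrast,
        reference={species_column: focal_parent, assay_column: mrna_level},
    )
    sf = size_factors(sub)
    res = nb_wald_fit(sub, sf, spec, samples=sheet, dispersion=dispersion)
    if shrink:
        est = res["log2FoldChange"].dropna()
        prior_var = max(float(est.var(ddof=1)), 1e-6) if len(est) > 1 else 1.0
        lam = prior_var / (prior_var + res["lfcSE"] ** 2)
        res["log2FoldChange_shrunk"] = res["log2FoldChange"] * lam
    return res
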