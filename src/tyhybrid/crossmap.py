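"""Mapping specificity between orthologous Ty families and count correction.

Orthologous families (e.g. Ty1 of S. cerevisiae vs S. paradoxus) are
similar enough that a fraction of reads from one maps onto the other's
reference — non-specific (cross-) mapping. Parental libraries quantify it
cleanly: in a single-species sample the cognate family's reference can
only receive reads by cross-mapping, so the rate is simply the cognate
share of the family's reads. Counts on the donor family can then be
restored by a deterministic scalar inflation, and a family overwhelmed by
reciprocal contamination (the low-expression member of a very asymmetric
pair) can be flagged for exclusion.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tyhybrid.annotations import Feature

logger = logging.getLogger(__name__)

IDENTITY_WINDOW = 100

#: Exclusion rule for a contamination-dominated family: flag the sink when
#: the cognate (donor) family is expressed at least ``expression_ratio``
#: fold higher and the donor->sink rate is at least ``min_rate``.
DEFAULT_EXCLUSION = {"expression_ratio": 5.0, "min_rate": 0.05}


# ---------------------------------------------------------------------------
# Windowed identity


def windowed_identity(
    msa: Sequence[tuple],
    window: int = IDENTITY_WINDOW,
) -> pd.DataFrame:
    """Mean pairwise interspecific identity (%) in alignment windows.

    ``msa`` is a list of ``(species, aligned_sequence)`` with equal-length
    gapped sequences from at least two species. The alignment is split
    into non-overlapping windows of alignment columns; per window and
    interspecific pair, identity = 1 - mismatches / compared positions,
    counted only over columns where both sequences have a base (indel
    columns are ignored). The window value averages over all interspecific
    pairs; windows with no comparable positions are missing (NaN).
    """
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned sequences")
    species = {sp for sp, _ in msa}
    if len(species) < 2:
        raise ValueError("need sequences from at least 2 species")
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    aln_len = lengths.pop()
    if aln_len < window:
        logger.info("alignment (%d) shorter than one window (%d): single "
                    "truncated window", aln_len, window)

    pairs = [
        (i, j)
        for i in range(len(msa))
        for j in range(i + 1, len(msa))
        if msa[i][0] != msa[j][0]
    ]
    arrs = [np.frombuffer(s.upper().encode(), dtype="S1") for _, s in msa]
    gap = np.array([b"-", b"."])

    rows = []
    n_windows = max(1, -(-aln_len // window))
    for w in range(n_windows):
        lo, hi = w * window, min((w + 1) * window, aln_len)
        vals = []
        for i, j in pairs:
            a, b = arrs[i][lo:hi], arrs[j][lo:hi]
            both = ~(np.isin(a, gap) | np.isin(b, gap))
            n = int(both.sum())
            if n == 0:
                continue
            mism = int((a[both] != b[both]).sum())
            vals.append(100.0 * (1.0 - mism / n))
        rows.append(
            {"window": w, "start": lo, "end": hi,
             "identity": float(np.mean(vals)) if vals else np.nan,
             "n_pairs": len(vals)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-mapping rates


@dataclasses.dataclass
class CrossmapRates:
    """rate[source -> target]: fraction of source-family reads assigned to
    the target (cognate) reference, estimated from parental libraries."""

    rates: dict  # (source, target) -> float in [0, 1]

    def get(self, source: str, target: str) -> float:
        key = (source, target)
        if key not in self.rates:
            raise KeyError(f"no cross-mapping rate for {source} -> {target}")
        return self.rates[key]


def estimate_crossmap_rates(
    parent_counts: pd.DataFrame,
    family_pairs: Sequence[tuple],
    parental_samples: Mapping[str, Sequence[str]] | None = None,
) -> CrossmapRates:
    """Estimate rates from single-species libraries counted on own + cognate
    references.

    ``family_pairs`` lists ``(own_feature, cognate_feature)`` per
    direction; for each, rate = cognate / (own + cognate) with counts
    pooled (summed) over the replicate columns listed in
    ``parental_samples[own_feature]`` (all columns if omitted). In a
    parental sample the cognate reference can receive reads only by
    cross-mapping, which is what makes this an estimate of the rate. Zero
    totals give a missing (NaN) rate.
    """
    rates = {}
    for own, cognate in family_pairs:
        if parental_samples is not None:
            cols = list(parental_samples[own])
        else:
            cols = list(parent_counts.columns)
        own_total = float(parent_counts.loc[own, cols].sum())
        cog_total = float(parent_counts.loc[cognate, cols].sum())
        total = own_total + cog_total
        if total == 0:
            logger.info("no reads for %s/%s: rate undefined", own, cognate)
            rates[(own, cognate)] = float("nan")
        else:
            rates[(own, cognate)] = cog_total / total
    return CrossmapRates(rates)


def correct_counts(
    counts: pd.DataFrame,
    rates: CrossmapRates,
    target_family: str,
    sink_family: str,
) -> pd.DataFrame:
    """Restore reads the target family lost to its cognate reference.

    adjusted(target) = observed(target) * (1 + rate[target -> sink]),
    applied per sample to raw counts (before normalization). The rest of
    the matrix is unchanged.
    """
    rate = rates.get(target_family, sink_family)
    if not np.isfinite(rate):
        raise ValueError(
            f"cross-mapping rate {target_family} -> {sink_family} is missing"
        )
    out = counts.copy()
    out.loc[target_family] = counts.loc[target_family] * (1.0 + rate)
    return out


def flag_excluded_families(
    counts: pd.DataFrame,
    rates: CrossmapRates,
    criteria: Mapping | None = None,
) -> list:
    """Families to exclude as contamination-dominated sinks.

    A family is flagged when its cognate is expressed at least
    ``expression_ratio`` fold higher (total counts) and the cognate's
    cross-mapping rate onto it is at least ``min_rate`` — the situation
    where non-specific mapping from the abundant cognate swamps the
    family's own signal.
    """
    crit = dict(DEFAULT_EXCLUSION, **(criteria or {}))
    excluded = []
    for (source, sink), rate in rates.rates.items():
        if not np.isfinite(rate) or rate < crit["min_rate"]:
            continue
        if source not in counts.index or sink not in counts.index:
            continue
        src_total = float(counts.loc[source].sum())
        sink_total = float(counts.loc[sink].sum())
        if sink_total == 0 or src_total / max(sink_total, 1e-300) >= crit[
            "expression_ratio"
        ]:
            excluded.append(sink)
    return sorted(set(excluded))


# ---------------------------------------------------------------------------
# Region masking for counting


def mask_region_for_family(
    annotation: Sequence[Feature],
    family: str,
    region: tuple,
) -> list:
    """Truncate a family's counting feature to exclude a reference region.

    ``region`` is a half-open interval on the family's pseudo-chromosome.
    The family's transcript feature is clipped to the part outside the
    region (used e.g. to restrict a family to its POL-specific portion
    when its GAG region cross-maps too heavily). An empty region leaves
    the annotation unchanged.
    """
    start, end = region
    if start >= end:
        return list(annotation)
    out = []
    for f in annotation:
        if f.attr("transcript_id") != family or f.kind != "transcript":
            out.append(f)
            continue
        if not (f.start <= start and end <= f.end):
            raise ValueError(
                f"region [{start}, {end}) outside feature "
                f"[{f.start}, {f.end}) of {family}"
            )
        pieces = []
        if f.start < start:
            pieces.append(dataclasses.replace(f, end=start))
        if end < f.end:
            pieces.append(dataclasses.replace(f, start=end))
        if not pieces:
            raise ValueError(f"masking the whole feature of {family}")
        out.extend(pieces)
    return out
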