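"""A minimal center-star multiple aligner.

Consensus building consumes pre-aligned sequences; producing a production
alignment is the caller's concern (any external aligner works). This
center-star implementation exists so the package can align the small,
closely related copy sets that arise in consensus construction and in
tests without an external dependency. It is not meant for divergent or
large inputs.
"""

from __future__ import annotations

from typing import Sequence

from Bio import Align


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def progressive_align(seqs: Sequence[str]) -> list[str]:
    """Align sequences by pairwise alignment to a center sequence.

    The longest sequence is the center. Each other sequence is aligned to
    it globally; gaps opened in the center by any pairwise alignment are
    propagated to all rows ("once a gap, always a gap").
    """
    seqs = [s.upper() for s in seqs]
    if len(seqs) < 2:
        return list(seqs)
    if len({len(s) for s in seqs}) == 1 and len(seqs[0]) > 0:
        # Equal-length inputs are treated as already columnwise comparable.
        return list(seqs)

    center_idx = max(range(len(seqs)), key=lambda i: len(seqs[i]))
    center = seqs[center_idx]
    aligner = _global_aligner()

    # Pairwise alignments of every other sequence to the center.
    pair_rows = {}  # index -> (center_row, seq_row)
    for i, s in enumerate(seqs):
        if i == center_idx:
            continue
        aln = aligner.align(center, s)[0]
        c_row, s_row = str(aln[0]), str(aln[1])
        pair_rows[i] = (c_row, s_row)

    # Build the merged gap structure of the center: at each center position,
    # the maximum number of insertions any pairwise alignment places there.
    ins_before = [0] * (len(center) + 1)
    for c_row, _ in pair_rows.values():
        pos = 0
        run = 0
        for ch in c_row:
            if ch == "-":
                run += 1
            else:
                ins_before[pos] = max(ins_before[pos], run)
                run = 0
                pos += 1
        ins_before[len(center)] = max(ins_before[len(center)], run)

    def expand(c_row: str, s_row: str) -> str:
        """Re-space one pairwise row onto the merged center coordinates."""
        out = []
        pos = 0
        run_chars: list[str] = []
        for c_ch, s_ch in zip(c_row, s_row):
            if c_ch == "-":
                run_chars.append(s_ch)
            else:
                out.append("-" * (ins_before[pos] - len(run_chars)))
                out.extend(run_chars)
                run_chars = []
                out.append(s_ch)
                pos += 1
        out.append("-" * (ins_before[len(center)] - len(run_chars)))
        out.extend(run_chars)
        return "".join(out)

    rows = [""] * len(seqs)
    center_row = expand("".join(center), "".join(center))
    rows[center_idx] = center_row
    for i, (c_row, s_row) in pair_rows.items():
        rows[i] = expand(c_row, s_row)
    assert len({len(r) for r in rows}) == 1
    return rows
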