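"""Synthetic data with known truth for every pipeline stage.

The generator emulates the study system: two diverged yeast-like parental
genomes carrying full-length Ty elements and solo LTRs of several
families, hybrid samples combining both subgenomes, per-family expression
with negative-binomial replicate noise, and reads in the three library
dialects (3'-end paired-end with poly-T starts, reverse-stranded
paired-end, single-end mRNA plus ribosome-protected fragments with 3-nt
periodicity and length-dependent 5' offsets). Reads are emitted
pre-aligned (ground-truth SAM) because short-read alignment is outside
the pipeline's scope; a configurable cross-mapping rate places a fraction
of orthologous-family reads on the cognate family's pseudo-chromosome,
mimicking non-specific mapping between closely related families.

Planted Ty elements follow the canonical full-length layout: the GAG
start codon 40 bp upstream of the 5' LTR end, the POL stop codon 25 bp
upstream of the 3' LTR, and POL overlapping GAG's 3' portion in a
different reading frame (the programmed-frameshift arrangement).
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from tyhybrid.annotations import Feature, TeAnnotationRecord, make_feature, revcomp
from tyhybrid.hybrid import HybridReference
from tyhybrid.reference import OrfInterval, STOP_CODONS, TyFamilyReference

BASES = np.array(list("ACGT"))
_STOPS = tuple(sorted(STOP_CODONS))
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

PARENT_TAGS = ("p1", "p2")


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Derive an independent, label-keyed RNG stream from the run seed.

    Streams are keyed by (seed, crc32(label)) so adding a new stage never
    perturbs the draws of earlier stages.
    """
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# Configuration


@dataclasses.dataclass
class FamilySpec:
    """Copy numbers, geometry and expression of one Ty family."""

    parents: tuple = PARENT_TAGS
    n_full: int = 2
    n_solo: int = 2
    internal_len: int = 5200
    ltr_len: int = 334
    gagless: bool = False
    mean: float = 500.0          # parental expected count per replicate
    fold_change: float = 1.0     # hybrid / parent expression multiplier


def default_families() -> dict:
    """Family content echoing the study system: Ty1 and Ty3 orthologous in
    both parents, Tsu4 private to parent2, plus a GAG-less Ty5-like family."""
    return {
        "Ty1": FamilySpec(parents=("p1", "p2"), n_full=2, n_solo=2, mean=800.0),
        "Ty3": FamilySpec(parents=("p1", "p2"), n_full=1, n_solo=1, mean=300.0),
        "Tsu4": FamilySpec(parents=("p2",), n_full=1, n_solo=1, mean=400.0),
        "Ty5": FamilySpec(parents=("p2",), n_full=1, n_solo=0, gagless=True,
                          mean=150.0),
    }


@dataclasses.dataclass
class SimConfig:
    seed: int = 0
    # genomes
    n_genes: int = 40
    gene_len: int = 900              # coding nt incl. start and stop codons
    n_contigs: int = 2
    spacer_len: int = 300
    families: dict = dataclasses.field(default_factory=default_families)
    divergence: float = 0.10         # substitution fraction between orthologs
    intra_divergence: float = 0.02   # within-family copy divergence
    # expression
    gene_mean_log: float = math.log(200.0)
    gene_mean_sd: float = 1.0
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    # libraries
    read_len_pe: int = 36            # 3'-end paired-end dialect
    read_len_stranded: int = 50
    read_len_mrna: int = 50
    fragment_len: int = 180
    fragment_sd: int = 20
    polyt_frac: float = 0.8
    rpf_length_probs: dict = dataclasses.field(
        default_factory=lambda: {27: 0.05, 28: 0.35, 29: 0.25, 30: 0.20,
                                 31: 0.10, 32: 0.05}
    )
    rpf_offsets: dict = dataclasses.field(
        default_factory=lambda: {27: 11, 28: 12, 29: 12, 30: 12, 31: 13, 32: 13}
    )
    #: relative ribosome occupancy of the initiation codon vs elongation
    #: codons; produces the start-codon metagene peak offsets are read from
    rpf_start_bias: float = 8.0
    crossmap_rate: float = 0.0
    secondary_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 0.5):
            raise ValueError(
                f"divergence must be in [0, 0.5); got {self.divergence} "
                "(higher values are unrealistic and break mapping assumptions)"
            )
        for name, rate in (
            ("crossmap_rate", self.crossmap_rate),
            ("polyt_frac", self.polyt_frac),
            ("secondary_rate", self.secondary_rate),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]; got {rate}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for spec in self.families.values():
            if spec.mean <= 0:
                raise ValueError("family expression means must be > 0")


# ---------------------------------------------------------------------------
# Constrained sequence construction


@dataclasses.dataclass(frozen=True)
class _OrfLayout:
    """ORF constraint set on a full-element coordinate system."""

    gag: tuple | None     # (start, end) half-open
    pol: tuple | None
    ltr5_end: int = 0

    def _codon_requirement(self, orf, p):
        start, end = orf
        if not (start <= p < end):
            return None
        cstart = start + 3 * ((p - start) // 3)
        if cstart == start:
            return cstart, "ATG"
        if cstart == end - 3:
            return cstart, "STOP"
        return cstart, "NONSTOP"

    def requirements_at(self, p: int):
        out = []
        for orf in (self.gag, self.pol):
            if orf is not None:
                req = self._codon_requirement(orf, p)
                if req is not None:
                    out.append(req)
        return out


def _codon_ok(seq: list, cstart: int, required: str) -> bool:
    codon = "".join(seq[cstart:cstart + 3])
    if required == "ATG":
        return codon == "ATG"
    if required == "STOP":
        return codon in STOP_CODONS
    return codon not in STOP_CODONS


def _ok_at(seq: list, p: int, layout: _OrfLayout) -> bool:
    return all(_codon_ok(seq, c, r) for c, r in layout.requirements_at(p))


def _write_codon(seq: list, cstart: int, codon: str) -> None:
    seq[cstart:cstart + 3] = list(codon)


def _repair_codon(seq: list, cstart: int, required: str, layout: _OrfLayout,
                  rng: np.random.Generator) -> None:
    """Mutate minimally so the codon at cstart satisfies its requirement
    without breaking any overlapping-frame requirement."""
    if _codon_ok(seq, cstart, required) and all(
        _ok_at(seq, p, layout) for p in range(cstart, cstart + 3)
    ):
        return
    if required in ("ATG", "STOP"):
        choices = ["ATG"] if required == "ATG" else list(_STOPS)
        rng.shuffle(choices)
        backup = seq[cstart:cstart + 3]
        for codon in choices:
            _write_codon(seq, cstart, codon)
            if all(_ok_at(seq, p, layout) for p in range(cstart, cstart + 3)):
                return
        seq[cstart:cstart + 3] = backup
        raise RuntimeError("could not satisfy forced-codon constraint")
    # NONSTOP: try single-base changes
    positions = list(range(cstart, cstart + 3))
    rng.shuffle(positions)
    for p in positions:
        orig = seq[p]
        bases = [b for b in "ACGT" if b != orig]
        rng.shuffle(bases)
        for b in bases:
            seq[p] = b
            if _codon_ok(seq, cstart, required) and all(
                _ok_at(seq, q, layout) for q in range(cstart, cstart + 3)
            ):
                return
        seq[p] = orig
    raise RuntimeError("could not repair codon to non-stop")


@dataclasses.dataclass
class PlantedFamily:
    """Canonical sequence and truth for one family in one parent."""

    family: str
    parent: str
    ltr: str
    internal: str
    gag: OrfInterval | None
    pol: OrfInterval | None

    @property
    def full(self) -> str:
        return self.ltr + self.internal + self.ltr

    def as_reference(self) -> TyFamilyReference:
        return TyFamilyReference(
            family_name=f"{self.family}_{self.parent}",
            internal_seq=self.internal,
            ltr5_seq=self.ltr,
            ltr3_seq=self.ltr,
            gag=self.gag,
            pol=self.pol,
        )

    def layout(self) -> _OrfLayout:
        gag = None if self.gag is None else (self.gag.start, self.gag.end)
        pol = None if self.pol is None else (self.pol.start, self.pol.end)
        return _OrfLayout(gag, pol, ltr5_end=len(self.ltr))


def _rand_seq(rng: np.random.Generator, n: int) -> list:
    return list(rng.choice(BASES, size=n))


def _scrub_window_atgs(seq: list, layout: _OrfLayout, window: tuple,
                       frames: Sequence[int], rng: np.random.Generator,
                       keep: int | None) -> None:
    """Remove ATG triplets in the given frames inside a window, except at
    ``keep``; prevents spurious GAG start candidates near the 5' LTR end."""
    lo, hi = window
    for p in range(max(0, lo), min(len(seq) - 2, hi)):
        if p == keep or (p % 3) not in frames:
            continue
        if "".join(seq[p:p + 3]) == "ATG":
            for q in (p, p + 1, p + 2):
                orig = seq[q]
                bases = [b for b in "ACGT" if b != orig]
                rng.shuffle(bases)
                done = False
                for b in bases:
                    seq[q] = b
                    if _ok_at(seq, q, layout) and "".join(seq[p:p + 3]) != "ATG":
                        done = True
                        break
                if done:
                    break
                seq[q] = orig


def plant_family(rng: np.random.Generator, family: str, parent: str,
                 spec: FamilySpec) -> PlantedFamily:
    """Construct a canonical full-length element with exact ORF geometry."""
    ltr_len = spec.ltr_len
    internal_len = spec.internal_len
    gag_start = ltr_len - 40
    gag_len = 1320

    if spec.gagless:
        gag = None
        pol_end = ltr_len + internal_len - 25
        pol_start = ltr_len + 201
        pol_start += (pol_end - pol_start) % 3
    else:
        gag = (gag_start, gag_start + gag_len)
        pol_end = ltr_len + internal_len - 25
        # POL must sit in a different frame from GAG; its frame equals
        # pol_end mod 3, so nudge the internal length until frames differ.
        while pol_end % 3 == gag_start % 3:
            internal_len += 1
            pol_end = ltr_len + internal_len - 25
        pol_start = gag[1] - 38
        pol_start -= (pol_start - pol_end) % 3

    pol = (pol_start, pol_end)
    layout = _OrfLayout(gag, pol, ltr5_end=ltr_len)

    ltr = _rand_seq(rng, ltr_len)
    full = ltr + _rand_seq(rng, internal_len) + list(ltr)

    # POL first: contiguous codons in its own frame.
    _write_codon(full, pol_start, "ATG")
    for c in range(pol_start + 3, pol_end - 3, 3):
        _write_codon(full, c, _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))])
    _write_codon(full, pol_end - 3, _STOPS[rng.integers(len(_STOPS))])

    # GAG second: codons clear of POL written directly, overlap repaired.
    if gag is not None:
        for c in range(gag[0], gag[1], 3):
            if c == gag[0]:
                req = "ATG"
            elif c == gag[1] - 3:
                req = "STOP"
            else:
                req = "NONSTOP"
            if c + 3 <= pol_start:
                codon = {"ATG": "ATG"}.get(req)
                if codon is None:
                    codon = (
                        _STOPS[rng.integers(len(_STOPS))]
                        if req == "STOP"
                        else _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
                    )
                _write_codon(full, c, codon)
            else:
                _repair_codon(full, c, req, layout, rng)

    # Terminate the reading frames immediately upstream of each planted
    # start codon so no earlier in-frame ATG can extend the ORF.
    for orf_start in filter(None, [None if gag is None else gag[0], pol_start]):
        for upstream in (orf_start - 3, orf_start - 6):
            if upstream < 0:
                break
            try:
                _repair_codon(full, upstream, "STOP", layout, rng)
                break
            except RuntimeError:
                continue

    # No competing GAG start candidates upstream of the real one.
    if gag is not None:
        _scrub_window_atgs(
            full, layout, (ltr_len - 100, gag_start), frames=[gag_start % 3],
            rng=rng, keep=gag_start,
        )
    else:
        _scrub_window_atgs(
            full, layout, (ltr_len - 100, ltr_len + 100), frames=[0, 1, 2],
            rng=rng, keep=None,
        )

    # The two LTRs must stay identical (young-element layout); the GAG start
    # lies inside the 5' LTR, so copy the edited 5' LTR to the 3' end and
    # scrub its gag-frame ATGs so the 3' copy cannot seed a spurious ORF.
    ltr_seq = full[:ltr_len]
    full[ltr_len + internal_len:] = list(ltr_seq)

    planted = PlantedFamily(
        family=family,
        parent=parent,
        ltr="".join(ltr_seq),
        internal="".join(full[ltr_len:ltr_len + internal_len]),
        gag=None if gag is None else OrfInterval(*gag),
        pol=OrfInterval(*pol),
    )
    _verify_layout(planted)
    return planted


def _verify_layout(p: PlantedFamily) -> None:
    seq = p.full
    for orf in (p.gag, p.pol):
        if orf is None:
            continue
        assert seq[orf.start:orf.start + 3] == "ATG"
        assert seq[orf.end - 3:orf.end] in STOP_CODONS
        for c in range(orf.start, orf.end - 3, 3):
            assert seq[c:c + 3] not in STOP_CODONS, (p.family, c)


def mutate_constrained(seq: str, layout: _OrfLayout, rng: np.random.Generator,
                       rate: float) -> tuple:
    """Substitute ~rate of sites while preserving ORF constraints.

    Returns (mutated sequence, number of realized substitutions). Target
    positions whose every alternative base violates a constraint are
    skipped (rare), so the realized rate can fall marginally short.
    """
    chars = list(seq)
    n_target = int(round(rate * len(chars)))
    if n_target == 0:
        return seq, 0
    positions = rng.choice(len(chars), size=n_target, replace=False)
    realized = 0
    for p in positions:
        p = int(p)
        orig = chars[p]
        bases = [b for b in "ACGT" if b != orig]
        rng.shuffle(bases)
        for b in bases:
            chars[p] = b
            if _ok_at(chars, p, layout):
                realized += 1
                break
            chars[p] = orig
    return "".join(chars), realized


# ---------------------------------------------------------------------------
# Genome generation


@dataclasses.dataclass
class SimGenomes:
    """Parental assemblies plus complete planting truth."""

    config: SimConfig
    assemblies: dict            # parent tag -> {contig: seq}
    gene_features: dict         # parent tag -> [Feature] (CDS transcripts)
    te_records: dict            # parent tag -> [TeAnnotationRecord]
    planted: dict               # (parent, family) -> PlantedFamily
    copy_divergence: dict       # (parent, family) -> [realized divergence/copy]

    def ty_library(self, parent: str) -> list:
        return [
            pf.as_reference()
            for (tag, _), pf in sorted(self.planted.items())
            if tag == parent
        ]

    def combined_ty_library(self) -> list:
        return [pf.as_reference() for _, pf in sorted(self.planted.items())]


def _make_gene(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3
    body = [
        _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
        for _ in range(n_codons - 2)
    ]
    return "ATG" + "".join(body) + _STOPS[rng.integers(len(_STOPS))]


def generate_genomes(config: SimConfig) -> SimGenomes:
    """Deterministically build both parental genomes and their truth.

    Orthologous families (present in both parents) are planted in parent1
    and derived for parent2 by constrained substitution at the configured
    divergence; within-parent copies beyond the first diverge at the
    intra-family rate, so the first copy is always the least-diverged
    (representative) one.
    """
    rng = rng_for(config.seed, "genomes")
    assemblies: dict = {}
    gene_features: dict = {}
    te_records: dict = {}
    planted: dict = {}
    copy_div: dict = {}

    # Canonical family sequences.
    for family in sorted(config.families):
        spec = config.families[family]
        first = spec.parents[0]
        base = plant_family(rng_for(config.seed, f"family:{family}"),
                            family, first, spec)
        planted[(first, family)] = base
        for other in spec.parents[1:]:
            mrng = rng_for(config.seed, f"ortholog:{family}:{other}")
            full, _ = mutate_constrained(base.full, base.layout(), mrng,
                                         config.divergence)
            ltr_len, internal_len = len(base.ltr), len(base.internal)
            # keep the two LTRs identical in the ortholog as well
            ltr = full[:ltr_len]
            planted[(other, family)] = PlantedFamily(
                family=family, parent=other, ltr=ltr,
                internal=full[ltr_len:ltr_len + internal_len],
                gag=base.gag, pol=base.pol,
            )

    for tag in PARENT_TAGS:
        grng = rng_for(config.seed, f"genome:{tag}")
        contigs: dict = {}
        feats: list = []
        tes: list = []
        gene_ids = [f"g{idx:04d}_{tag}" for idx in range(config.n_genes)]
        genes_per_contig = np.array_split(np.array(gene_ids), config.n_contigs)

        # Family copies destined for this parent.
        inserts = []  # (kind, family, seq, strand, element_label)
        for family in sorted(config.families):
            spec = config.families[family]
            if tag not in spec.parents:
                continue
            base = planted[(tag, family)]
            divs = []
            for i in range(spec.n_full):
                crng = rng_for(config.seed, f"copy:{tag}:{family}:{i}")
                if i == 0:
                    seq, realized = base.full, 0
                else:
                    seq, realized = mutate_constrained(
                        base.full, base.layout(), crng, config.intra_divergence
                    )
                divs.append(realized / len(base.full))
                strand = "+" if i % 2 == 0 else "-"
                inserts.append(("full", family, seq, strand, f"{family}_{tag}_e{i}"))
            for i in range(spec.n_solo):
                srng = rng_for(config.seed, f"solo:{tag}:{family}:{i}")
                seq, _ = mutate_constrained(
                    base.ltr, _OrfLayout(None, None), srng, config.intra_divergence
                )
                inserts.append(("solo", family, seq, "+", f"{family}_{tag}_s{i}"))
            copy_div[(tag, family)] = divs

        insert_sets = np.array_split(np.arange(len(inserts)), config.n_contigs)

        for ci in range(config.n_contigs):
            contig = f"chr{ci + 1}"
            parts: list = []
            pos = 0

            def spacer():
                nonlocal pos
                s = "".join(grng.choice(BASES, size=config.spacer_len))
                parts.append(s)
                pos += len(s)

            spacer()
            for gid in genes_per_contig[ci]:
                gseq = _make_gene(grng, config.gene_len)
                feats.append(
                    make_feature(contig, pos, pos + len(gseq), "+", "CDS",
                                 transcript_id=str(gid))
                )
                parts.append(gseq)
                pos += len(gseq)
                spacer()
            for ii in insert_sets[ci]:
                kind, family, seq, strand, label = inserts[int(ii)]
                placed = revcomp(seq) if strand == "-" else seq
                spec = config.families[family]
                if kind == "full":
                    L, I = spec.ltr_len, len(seq) - 2 * spec.ltr_len
                    if strand == "+":
                        segs = [("LTR", 0, L), ("internal", L, L + I),
                                ("LTR", L + I, L + I + L)]
                    else:
                        segs = [("LTR", 0, L), ("internal", L, L + I),
                                ("LTR", L + I, L + I + L)]
                    for part, s0, s1 in segs:
                        tes.append(
                            TeAnnotationRecord(contig, pos + s0, pos + s1, strand,
                                               family, part, label)
                        )
                else:
                    tes.append(
                        TeAnnotationRecord(contig, pos, pos + len(seq), strand,
                                           family, "LTR", label)
                    )
                parts.append(placed)
                pos += len(placed)
                spacer()
            contigs[contig] = "".join(parts)

        assemblies[tag] = contigs
        gene_features[tag] = feats
        te_records[tag] = tes

    return SimGenomes(config, assemblies, gene_features, te_records, planted,
                      copy_div)


# ---------------------------------------------------------------------------
# Counts


def nb_counts(mean: np.ndarray, dispersion: float,
              rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with Var = mean + dispersion * mean^2.

    dispersion 0 is the Poisson limit.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-300) * dispersion)
    return rng.poisson(lam)


def make_sample_sheet(config: SimConfig, groups=("p1", "p2", "hybrid"),
                      library: str = "stranded_PE") -> pd.DataFrame:
    rows = []
    for group in groups:
        for rep in range(1, config.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{group}_r{rep}",
                    "species": group,
                    "replicate": rep,
                    "library": library,
                }
            )
    sheet = pd.DataFrame(rows).set_index("sample_id", drop=False)
    sheet.index.name = None
    return sheet


@dataclasses.dataclass
class SimCounts:
    mean: pd.DataFrame      # expected counts, features x samples
    counts: pd.DataFrame    # NB draws, features x samples
    samples: pd.DataFrame


def expected_means(config: SimConfig, genomes: SimGenomes,
                   samples: pd.DataFrame) -> pd.DataFrame:
    """Per-feature per-sample expected counts.

    Parent samples express their own genes and Ty families; hybrid samples
    express both subgenomes, with family means scaled by the configured
    fold changes. Gene means are drawn once per run from a log-normal.
    """
    erng = rng_for(config.seed, "expression")
    feature_rows = []
    for tag in PARENT_TAGS:
        for f in genomes.gene_features[tag]:
            feature_rows.append((f.attr("transcript_id"), tag, "gene",
                                 float(np.exp(erng.normal(config.gene_mean_log,
                                                          config.gene_mean_sd)))))
    for (tag, family), pf in sorted(genomes.planted.items()):
        spec = config.families[family]
        feature_rows.append((f"{family}_{tag}", tag, "ty", spec.mean))

    idx = [r[0] for r in feature_rows]
    mean = pd.DataFrame(0.0, index=idx, columns=samples["sample_id"])
    for fid, tag, kind, base_mean in feature_rows:
        family = fid.rsplit("_", 1)[0] if kind == "ty" else None
        for sid, row in samples.iterrows():
            grp = row["species"]
            if grp == tag:
                mean.loc[fid, sid] = base_mean
            elif grp == "hybrid":
                fc = config.families[family].fold_change if kind == "ty" else 1.0
                mean.loc[fid, sid] = base_mean * fc
    return mean


def simulate_counts(config: SimConfig, genomes: SimGenomes | None = None,
                    samples: pd.DataFrame | None = None) -> SimCounts:
    if genomes is None:
        genomes = generate_genomes(config)
    if samples is None:
        samples = make_sample_sheet(config)
    mean = expected_means(config, genomes, samples)
    crng = rng_for(config.seed, "counts")
    counts = pd.DataFrame(
        nb_counts(mean.to_numpy(), config.nb_dispersion, crng),
        index=mean.index, columns=mean.columns,
    )
    return SimCounts(mean=mean, counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# Reads


@dataclasses.dataclass
class SimReads:
    sam_paths: dict          # sample_id -> SAM path
    fastq_paths: dict        # sample_id -> path or (path1, path2)
    truth: pd.DataFrame      # one row per read pair/fragment


def _transcript_features(reference: HybridReference) -> list:
    return [f for f in reference.features if f.kind in ("transcript", "CDS")
            and f.attr("transcript_id") is not None]


def _qual(n: int) -> str:
    return "I" * n


class _SamWriter:
    def __init__(self, path, reference: HybridReference):
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in reference.contigs.items()
            ],
        }
        self.f = pysam.AlignmentFile(str(path), "w", header=header)
        self.tid = {name: i for i, name in enumerate(reference.contigs)}

    def write_single(self, qname, contig, pos, seq, reverse=False,
                     secondary=False):
        a = pysam.AlignedSegment(self.f.header)
        a.query_name = qname
        a.query_sequence = seq
        a.flag = (16 if reverse else 0) | (256 if secondary else 0)
        a.reference_id = self.tid[contig]
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigar = [(0, len(seq))]
        a.query_qualities = pysam.qualitystring_to_array(_qual(len(seq)))
        self.f.write(a)

    def write_pair(self, qname, contig, pos1, seq1, rev1, pos2, seq2, rev2,
                   secondary=False):
        tlen = (max(pos1 + len(seq1), pos2 + len(seq2))
                - min(pos1, pos2))
        for idx, (pos, seq, rev, mpos, mrev) in enumerate(
            [(pos1, seq1, rev1, pos2, rev2), (pos2, seq2, rev2, pos1, rev1)]
        ):
            a = pysam.AlignedSegment(self.f.header)
            a.query_name = qname
            a.query_sequence = seq
            flag = 1 | 2  # paired, proper pair
            flag |= 64 if idx == 0 else 128
            if rev:
                flag |= 16
            if mrev:
                flag |= 32
            if secondary:
                flag |= 256
            a.flag = flag
            a.reference_id = self.tid[contig]
            a.reference_start = pos
            a.next_reference_id = self.tid[contig]
            a.next_reference_start = mpos
            a.template_length = tlen if pos <= mpos else -tlen
            a.mapping_quality = 60
            a.cigar = [(0, len(seq))]
            a.query_qualities = pysam.qualitystring_to_array(_qual(len(seq)))
            self.f.write(a)

    def close(self):
        self.f.close()


def _ortholog_map(reference: HybridReference, planted: Mapping) -> dict:
    """Pseudo-chromosome -> cognate pseudo-chromosome for orthologous
    families, resolved through the transcript features so the mapping holds
    in every dialect's contig naming."""
    fam_contig = {}
    for f in reference.features:
        tid = f.attr("transcript_id")
        if (reference.provenance.get(f.contig) == "ty_pseudo"
                and f.attr("part") == "internal" and tid is not None):
            fam_contig[tid] = f.contig
    out = {}
    fam_parents: dict = {}
    for (tag, family) in planted:
        fam_parents.setdefault(family, []).append(tag)
    for family, tags in fam_parents.items():
        if len(tags) == 2:
            a, b = sorted(tags)
            ca, cb = fam_contig.get(f"{family}_{a}"), fam_contig.get(f"{family}_{b}")
            if ca and cb:
                out[ca] = cb
                out[cb] = ca
    return out


def simulate_reads(
    config: SimConfig,
    reference: HybridReference,
    counts: pd.DataFrame,
    genomes: SimGenomes,
    out_dir,
    dialect: str | None = None,
    library: str = "stranded_PE",
) -> SimReads:
    """Emit FASTQ + ground-truth SAM for each sample column of ``counts``.

    Every read is placed at its true origin except that, for families with
    an ortholog in the other parent, a ``crossmap_rate`` fraction of reads
    is placed on the cognate pseudo-chromosome at the same offset. Truth
    rows record the true source feature and the placed contig.
    """
    dialect = dialect or reference.dialect
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    transcripts = {}
    for f in reference.features:
        tid = f.attr("transcript_id")
        if tid is not None and f.attr("part") != "LTR" and f.kind in (
            "transcript", "CDS",
        ):
            transcripts[tid] = f
    # In the three_prime dialect, the Ty transcript runs from the internal
    # start to the end of the 3' LTR (the canonical transcript extends into
    # the LTR), so extend Ty features to the pseudo-chromosome end.
    spans = {}
    for tid, f in transcripts.items():
        if dialect == "three_prime" and reference.provenance.get(f.contig) == "ty_pseudo":
            spans[tid] = (f.contig, f.start, len(reference.contigs[f.contig]))
        else:
            spans[tid] = (f.contig, f.start, f.end)

    ortho = _ortholog_map(reference, genomes.planted)
    ty_contigs = set(reference.pseudo_chromosomes)

    # Codon-frame sources for ribosome-protected fragments: genes use their
    # own CDS; Ty families use their GAG/POL CDS intervals so RPF P-sites
    # land on true codon starts of the element's ORFs.
    cds_by_contig: dict = {}
    for f in reference.features:
        if f.kind == "CDS" and f.attr("orf") is not None:
            cds_by_contig.setdefault(f.contig, []).append((f.start, f.end))

    rpf_lengths = np.array(sorted(config.rpf_length_probs))
    rpf_probs = np.array([config.rpf_length_probs[l] for l in rpf_lengths],
                         dtype=float)
    rpf_probs /= rpf_probs.sum()

    sam_paths: dict = {}
    fastq_paths: dict = {}
    truth_rows: list = []
    paired = dialect in ("three_prime", "separate")

    for sample in counts.columns:
        rng = rng_for(config.seed, f"reads:{dialect}:{library}:{sample}")
        sam_path = out / f"{sample}.{dialect}.sam"
        writer = _SamWriter(sam_path, reference)
        if paired:
            fq1 = open(out / f"{sample}_R1.fastq", "w")
            fq2 = open(out / f"{sample}_R2.fastq", "w")
            fastq_paths[sample] = (str(out / f"{sample}_R1.fastq"),
                                   str(out / f"{sample}_R2.fastq"))
        else:
            fq1 = open(out / f"{sample}.fastq", "w")
            fq2 = None
            fastq_paths[sample] = str(out / f"{sample}.fastq")

        n_read = 0
        for tid in counts.index:
            n = int(counts.loc[tid, sample])
            if n <= 0 or tid not in spans:
                continue
            contig, t0, t1 = spans[tid]
            cseq = reference.contigs[contig]
            crossable = contig in ty_contigs and contig in ortho
            feat = transcripts[tid]

            for _ in range(n):
                qname = f"{sample}:{n_read:08d}"
                n_read += 1
                place_contig = contig
                crossmapped = False
                if crossable and rng.random() < config.crossmap_rate:
                    place_contig = ortho[contig]
                    crossmapped = True
                place_len = len(reference.contigs[place_contig])

                if dialect == "three_prime":
                    rl = config.read_len_pe
                    frag = max(
                        2 * rl,
                        int(rng.normal(config.fragment_len, config.fragment_sd)),
                    )
                    frag = min(frag, t1 - t0)
                    # 3'-biased: fragment ends decay geometrically away from
                    # the transcript 3' end (alternative polyadenylation
                    # spreads real DS1 coverage well into internal sequences)
                    slack = max(0, t1 - t0 - frag)
                    back = min(int(rng.geometric(0.005)) - 1, slack)
                    f1 = t1 - back
                    f0 = f1 - frag
                    p1, p2 = f0, f1 - rl
                    seq1 = cseq[p1:p1 + rl]
                    seq2 = revcomp(cseq[p2:p2 + rl])
                    polyt = bool(rng.random() < config.polyt_frac)
                    if polyt:
                        seq2 = "TT" + seq2[2:]
                    pp1 = min(p1, place_len - rl)
                    pp2 = min(p2, place_len - rl)
                    writer.write_pair(qname, place_contig, pp1, seq1, False,
                                      pp2, seq2, True)
                    fq1.write(f"@{qname}\n{seq1}\n+\n{_qual(rl)}\n")
                    fq2.write(f"@{qname}\n{seq2}\n+\n{_qual(rl)}\n")
                    truth_rows.append(
                        (qname, sample, tid, contig, place_contig, p1,
                         crossmapped, polyt, frag)
                    )
                elif dialect == "separate":
                    rl = config.read_len_stranded
                    frag = max(
                        2 * rl,
                        int(rng.normal(config.fragment_len, config.fragment_sd)),
                    )
                    frag = min(frag, t1 - t0)
                    f0 = t0 + int(rng.integers(0, max(1, t1 - t0 - frag + 1)))
                    f1 = f0 + frag
                    # reverse-stranded: read2 sense, read1 antisense
                    p2, p1 = f0, f1 - rl
                    seq2 = cseq[p2:p2 + rl]
                    seq1 = revcomp(cseq[p1:p1 + rl])
                    pp1 = min(p1, place_len - rl)
                    pp2 = min(p2, place_len - rl)
                    writer.write_pair(qname, place_contig, pp1, seq1, True,
                                      pp2, seq2, False)
                    fq1.write(f"@{qname}\n{seq1}\n+\n{_qual(rl)}\n")
                    fq2.write(f"@{qname}\n{seq2}\n+\n{_qual(rl)}\n")
                    truth_rows.append(
                        (qname, sample, tid, contig, place_contig, f0,
                         crossmapped, False, frag)
                    )
                elif dialect == "five_prime" and library != "rpf_SE":
                    rl = config.read_len_mrna
                    span = max(1, t1 - t0 - rl + 1)
                    p = t0 + int(rng.integers(0, span))
                    seq = cseq[p:p + rl]
                    pp = min(p, place_len - rl)
                    writer.write_single(qname, place_contig, pp, seq)
                    fq1.write(f"@{qname}\n{seq}\n+\n{_qual(rl)}\n")
                    truth_rows.append(
                        (qname, sample, tid, contig, place_contig, p,
                         crossmapped, False, rl)
                    )
                elif dialect == "five_prime":  # ribosome-protected fragments
                    rl = int(rng.choice(rpf_lengths, p=rpf_probs))
                    offset = config.rpf_offsets[rl]
                    frames = cds_by_contig.get(contig) or [(feat.start, feat.end)]
                    if len(frames) == 1:
                        cds0, cds1 = frames[0]
                    else:
                        weights = np.array([(b - a) // 3 for a, b in frames],
                                           dtype=float)
                        k = int(rng.choice(len(frames), p=weights / weights.sum()))
                        cds0, cds1 = frames[k]
                    n_codons = (cds1 - cds0) // 3
                    # elevated occupancy at the initiation codon gives the
                    # start-codon metagene its peak
                    bias = max(config.rpf_start_bias, 1.0)
                    if rng.random() < bias / (bias + n_codons - 1):
                        codon = 0
                    else:
                        codon = int(rng.integers(1, n_codons))
                    psite = cds0 + 3 * codon
                    p = psite - offset
                    if p < 0 or p + rl > len(cseq):
                        continue
                    seq = cseq[p:p + rl]
                    pp = min(max(p, 0), place_len - rl)
                    writer.write_single(qname, place_contig, pp, seq)
                    fq1.write(f"@{qname}\n{seq}\n+\n{_qual(rl)}\n")
                    truth_rows.append(
                        (qname, sample, tid, contig, place_contig, p,
                         crossmapped, False, rl)
                    )
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")

                if config.secondary_rate and rng.random() < config.secondary_rate:
                    # plant a duplicate secondary record at a shifted position
                    if paired:
                        pass  # secondaries only planted for single-end reads
                    else:
                        shifted = max(0, pp - 50)
                        writer.write_single(f"{qname}", place_contig, shifted,
                                            seq, secondary=True)

        writer.close()
        fq1.close()
        if fq2 is not None:
            fq2.close()
        sam_paths[sample] = str(sam_path)

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "feature", "true_contig", "placed_contig",
                 "true_pos", "crossmapped", "polyt", "fragment_len"],
    )
    return SimReads(sam_paths=sam_paths, fastq_paths=fastq_paths, truth=truth)
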