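"""Configuration-driven orchestration of the full synthetic workflow.

``run_pipeline`` exercises every stage end-to-end on generated data:
simulate parental genomes, rebuild the Ty library from annotations,
hard-mask and concatenate the hybrid reference, simulate reads, count,
estimate and correct cross-mapping, test differential expression, and
summarize. All tabular outputs are TSV with one comment header line
carrying the package version and a hash of the configuration, and every
stage draws its randomness from streams derived from the single run seed,
so identical configurations reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from tyhybrid import __version__
from tyhybrid.annotations import write_fasta, write_te_annotations, write_features
from tyhybrid.crossmap import estimate_crossmap_rates, correct_counts
from tyhybrid.detest import Contrast, run_contrasts, summarize_contrasts
from tyhybrid.hybrid import MaskSpec, build_hybrid_reference, hard_mask, write_reference
from tyhybrid.quantify import CountOptions, build_count_matrix, compute_tpm, feature_lengths
from tyhybrid.reference import build_family_reference, write_ty_library
from tyhybrid.simulate import (
    PARENT_TAGS,
    SimConfig,
    generate_genomes,
    make_sample_sheet,
    simulate_counts,
    simulate_reads,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "tyhybrid_run"
    dialect: str = "separate"
    alpha: float = 0.05
    stranded: str = "reverse"        # counting mode for the separate dialect
    multimap: str = "fractional"
    min_fragment: int = 5
    crossmap_correct: bool = True
    sim: dict = dataclasses.field(default_factory=dict)  # SimConfig overrides

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def config_hash(self) -> str:
        # the output location is not a scientific parameter
        fields = {k: v for k, v in dataclasses.asdict(self).items()
                  if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(frame: pd.DataFrame, path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tyhybrid {__version__} config={config_hash}\n")
        frame.to_csv(fh, sep="\t")


def check_config_hash(path, expected: str) -> None:
    """Refuse a table produced under a different configuration."""
    with open(path) as fh:
        header = fh.readline()
    if f"config={expected}" not in header:
        raise ValueError(f"{path}: config hash mismatch (expected {expected})")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {"version": __version__, "config_hash": chash, "stages": {}}

    def stage(name):
        t0 = time.time()
        logger.info("stage %s", name)

        def done(**outputs):
            manifest["stages"][name] = {
                "outputs": {k: str(v) for k, v in outputs.items()},
                "seconds": round(time.time() - t0, 3),
            }

        return done

    # 1. simulate genomes
    done = stage("simulate_genomes")
    sim_cfg = config.sim_config()
    genomes = generate_genomes(sim_cfg)
    for tag in PARENT_TAGS:
        write_fasta(genomes.assemblies[tag], out / f"{tag}_genome.fasta")
        write_te_annotations(genomes.te_records[tag], out / f"{tag}_te.gff3")
        write_features(genomes.gene_features[tag], out / f"{tag}_genes.gff3")
    done(genomes=out)

    # 2. rebuild the Ty library from assemblies + annotations
    done = stage("build_reference")
    library = []
    for tag in PARENT_TAGS:
        families = sorted({r.family for r in genomes.te_records[tag]})
        for family in families:
            try:
                ref = build_family_reference(
                    genomes.assemblies[tag], genomes.te_records[tag],
                    family, species_tag=tag,
                )
            except ValueError:
                continue  # solo-LTR-only family in this parent
            library.append(ref)
    write_ty_library(library, out)
    done(library=out / "ty_library.fasta")

    # 3. mask and build the hybrid reference
    done = stage("build_genome")
    masked = {
        tag: hard_mask(
            genomes.assemblies[tag],
            MaskSpec.from_te_annotations(genomes.te_records[tag]),
        )
        for tag in PARENT_TAGS
    }
    reference = build_hybrid_reference(
        masked[PARENT_TAGS[0]],
        masked[PARENT_TAGS[1]],
        library,
        config.dialect,
        parent1_features=genomes.gene_features[PARENT_TAGS[0]],
        parent2_features=genomes.gene_features[PARENT_TAGS[1]],
        parent_tags=PARENT_TAGS,
    )
    write_reference(reference, out)
    done(reference=out / "hybrid_genome.fasta")

    # 4. simulate expression and reads
    done = stage("simulate_reads")
    samples = make_sample_sheet(sim_cfg)
    sim_counts = simulate_counts(sim_cfg, genomes, samples)
    reads = simulate_reads(sim_cfg, reference, sim_counts.counts, genomes,
                           out / "reads", dialect=config.dialect)
    _write_tsv(sim_counts.counts, out / "true_counts.tsv", chash)
    samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    done(reads=out / "reads")

    # 5. count
    done = stage("count")
    options = CountOptions(
        stranded=config.stranded if config.dialect == "separate" else "none",
        multimap=config.multimap,
        min_fragment=config.min_fragment,
    )
    counts = build_count_matrix(reads.sam_paths, reference.features, options)
    lengths = feature_lengths(reference.features)
    tpm = compute_tpm(counts, lengths.reindex(counts.index))
    _write_tsv(counts, out / "counts.tsv", chash)
    _write_tsv(tpm, out / "tpm.tsv", chash)
    done(counts=out / "counts.tsv", tpm=out / "tpm.tsv")

    # 6. cross-mapping estimation and correction
    done = stage("crossmap")
    ortho_pairs = []
    fam_parents: dict = {}
    for (tag, family) in genomes.planted:
        fam_parents.setdefault(family, []).append(tag)
    for family, tags in sorted(fam_parents.items()):
        if len(tags) == 2:
            a, b = sorted(tags)
            ortho_pairs.append((f"{family}_{a}", f"{family}_{b}"))
            ortho_pairs.append((f"{family}_{b}", f"{family}_{a}"))
    corrected = counts
    rates_frame = pd.DataFrame(columns=["source", "target", "rate"])
    if ortho_pairs:
        parental = {
            own: [s for s in counts.columns
                  if samples.loc[s, "species"] == own.rsplit("_", 1)[1]]
            for own, _ in ortho_pairs
        }
        rates = estimate_crossmap_rates(counts, ortho_pairs, parental)
        rates_frame = pd.DataFrame(
            [(s, t, r) for (s, t), r in rates.rates.items()],
            columns=["source", "target", "rate"],
        )
        if config.crossmap_correct:
            for source, target in ortho_pairs:
                rate = rates.rates[(source, target)]
                if pd.notna(rate) and rate > 0:
                    corrected = correct_counts(corrected, rates, source, target)
    _write_tsv(rates_frame.set_index("source"), out / "crossmap_rates.tsv", chash)
    _write_tsv(corrected, out / "counts_corrected.tsv", chash)
    done(rates=out / "crossmap_rates.tsv")

    # 7. differential expression: hybrid vs each parent
    done = stage("differential_expression")
    subgenome = pd.Series(
        {
            f.attr("transcript_id"): tag
            for tag in PARENT_TAGS
            for f in genomes.gene_features[tag]
        }
    )
    for (tag, family) in genomes.planted:
        subgenome[f"{family}_{tag}"] = tag
    contrasts = [
        Contrast(name=f"hybrid_vs_{tag}", focal_parent=tag, alpha=config.alpha)
        for tag in PARENT_TAGS
    ]
    results = run_contrasts(corrected, samples, subgenome, contrasts)
    for name, res in results.items():
        _write_tsv(res, out / f"de_{name}.tsv", chash)
    done(**{name: out / f"de_{name}.tsv" for name in results})

    # 8. report
    done = stage("report")
    ty_features = [f"{family}_{tag}" for (tag, family) in sorted(genomes.planted)]
    report = make_report(results, ty_features=ty_features, alpha=config.alpha)
    _write_tsv(report, out / "report.tsv", chash)
    done(report=out / "report.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def make_report(results: dict, ty_features=(), alpha: float = 0.05) -> pd.DataFrame:
    """Per-contrast counts of significantly up/down features and Ty families."""
    if not results:
        raise ValueError("no contrast tables to report on")
    return summarize_contrasts(results, ty_features=ty_features, alpha=alpha)
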