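"""End-to-end pipeline orchestration with seeded determinism and a run manifest.

Stage order follows the original analysis flowchart: bidirectional-identity
collapse -> ncRNA filter -> two-pass genome alignment (complete
nanochromosomes + optional chrM, then partial contigs) -> size, origin,
strand-balance and telomere-profile statistics.  Every stage's read counts
are conservation-checked and recorded in a JSON manifest together with the
seed and a config echo.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import synthdata
from ._util import read_fasta, write_fasta
from .aligncore import AlignPolicy, export_bedgraph, export_sam, run_two_pass
from .ncfilter import build_filter_set, filter_summary, partition_reads
from .readprep import PrepConfig, prep_fastq_pair
from .refbuild import (annotate_reference, build_concat, split_by_completeness,
                       write_offsets_table)
from .sizestats import length_histogram, modal_mapped_length, position_freq
from .strandprofile import (EnvelopeConfig, ProfileConfig, cv_table,
                            depletion_fold, empirical_band,
                            envelope_inside_fraction, pearson_r,
                            strand_count_table, telomere_end_profile)


@dataclass
class RunConfig:
    fastq1: str = ""
    fastq2: str = ""
    ncrna_fasta: str | None = None
    genome_fasta: str = ""          # auto-split into complete/partial records
    chrm_fasta: str | None = None
    out_dir: str = "macrna_out"
    label: str = "library"
    seed: int = 0
    telomere_unit: str = "GGGGTTTT"
    stringent_mm: int = 1
    lenient_mm: int = 3
    report_mode: str = "random_one"
    prep: PrepConfig = field(default_factory=PrepConfig)
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        for key, sub in (("prep", PrepConfig), ("envelope", EnvelopeConfig),
                         ("profile", ProfileConfig)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        return cls(**data)

    def validate(self) -> None:
        for name in ("fastq1", "fastq2", "genome_fasta"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p!r} does not exist")
        for name in ("ncrna_fasta", "chrm_fasta"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p!r} does not exist")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate(cfg: synthdata.GeneratorConfig, out_dir: str | Path,
             n_mds_range: tuple[int, int] = (2, 8),
             scrambled_frac: float = 0.3) -> dict[str, Path]:
    """Generate a full fixture bundle: genomes, loci, decoys, FASTQ, truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()
    genes = synthdata.gen_genome(cfg, rng)
    loci = []
    for g in genes:
        n_mds = int(rng.integers(*n_mds_range))
        try:
            loci.append(synthdata.gen_micro_locus(
                g, n_mds, scrambled=bool(rng.random() < scrambled_frac),
                rng=rng, gc=cfg.gc))
        except ValueError:
            warnings.warn(f"skipping micronuclear locus for short gene {g.id}")
    decoys = synthdata.gen_ncrna_decoys(cfg, rng)
    pool = synthdata.gen_small_rna_pool(genes, loci, cfg, rng, decoys=decoys)
    paths = {
        "genome": out / "genome.fasta",
        "loci": out / "micro_loci.fasta",
        "ncrna": out / "ncrna.fasta",
        "fastq1": out / "reads_1.fastq",
        "fastq2": out / "reads_2.fastq",
        "truth": out / "truth.tsv",
        "config": out / "generator_config.json",
    }
    write_fasta([(g.id, g.sequence) for g in genes], paths["genome"])
    write_fasta([(f"{l.gene_id}_micro", l.micro_sequence) for l in loci],
                paths["loci"])
    write_fasta(decoys, paths["ncrna"])
    synthdata.emit_paired_fastq(pool, cfg, paths["fastq1"], paths["fastq2"], rng)
    synthdata.write_truth_table(pool, paths["truth"])
    synthdata.write_config_echo(cfg, paths["config"])
    return paths


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not cfg.force:
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == _config_hash(cfg):
            return old  # completed run with identical config: no-op
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config_hash": _config_hash(cfg),
                      "stages": {}, "conservation": {}}

    # -- read preparation ----------------------------------------------------
    reads, prep_stats = prep_fastq_pair(cfg.fastq1, cfg.fastq2,
                                        cfg.prep, label=cfg.label)
    manifest["stages"]["prep"] = dataclasses.asdict(prep_stats)
    manifest["conservation"]["prep"] = prep_stats.conserved
    if not prep_stats.conserved:
        raise RuntimeError("read-preparation conservation check failed")

    # -- ncRNA filter --------------------------------------------------------
    fs = build_filter_set(cfg.ncrna_fasta, telomere_unit=cfg.telomere_unit,
                          max_mismatches=cfg.lenient_mm)
    ncrna, surviving = partition_reads(reads, fs)
    ok = (ncrna.total_reads + surviving.total_reads == reads.total_reads and
          ncrna.distinct_reads + surviving.distinct_reads == reads.distinct_reads)
    manifest["conservation"]["ncfilter"] = ok
    if not ok:
        raise RuntimeError("ncRNA filter partition is not exhaustive/exclusive")
    filter_summary(reads, ncrna, surviving).to_csv(
        out / "ncfilter_summary.tsv", sep="\t", index=False)
    surviving.write_fasta(out / "surviving_reads.fasta")
    ncrna.write_fasta(out / "ncrna_reads.fasta")
    manifest["stages"]["ncfilter"] = {
        "ncrna_total": ncrna.total_reads, "surviving_total": surviving.total_reads}

    # -- reference construction ---------------------------------------------
    records = read_fasta(cfg.genome_fasta)
    complete, partial = split_by_completeness(records, cfg.telomere_unit)
    chr1 = build_concat(complete, name="chr1")
    chr2 = build_concat(partial, name="chr2") if partial else None
    chrm = None
    if cfg.chrm_fasta:
        chrm = build_concat(read_fasta(cfg.chrm_fasta), name="chrM")
    ann = annotate_reference(records, cfg.telomere_unit)
    write_offsets_table(chr1, ann, out / "chr1_offsets.tsv")
    if chr2 is not None:
        write_offsets_table(chr2, ann, out / "chr2_offsets.tsv")
    manifest["stages"]["refbuild"] = {"chr1_records": chr1.n_records,
                                      "chr2_records":
                                          chr2.n_records if chr2 else 0}

    # -- two-pass alignment --------------------------------------------------
    policy = AlignPolicy(max_mismatches=cfg.stringent_mm,
                         report_mode=cfg.report_mode)
    hits, summary = run_two_pass(surviving, chr1, chr2, chrm, policy,
                                 seed=cfg.seed)
    manifest["conservation"]["align"] = summary.conserved
    if not summary.conserved:
        raise RuntimeError("alignment multiplicity accounting failed")
    pd.DataFrame([summary.to_row()]).to_csv(out / "mapping_summary.tsv",
                                            sep="\t", index=False)
    refs = [chr1] + ([chr2] if chr2 else []) + ([chrm] if chrm else [])
    export_sam(hits, surviving, refs, out / "hits.sam")
    export_bedgraph(hits, surviving, out / "fivep_plus.bedgraph",
                    out / "fivep_minus.bedgraph")
    manifest["stages"]["align"] = summary.to_row()

    # -- size statistics -----------------------------------------------------
    macro_records = set(chr1.record_ids) | (set(chr2.record_ids) if chr2
                                            else set())
    mapped = {s for s, hh in hits.items()
              if any(h.record_id in macro_records for h in hh)}
    hist = length_histogram(surviving, mapped)
    hist.to_csv(out / "length_histogram.tsv", sep="\t", index=False)
    modal = modal_mapped_length(hist)
    manifest["stages"]["sizestats"] = {"modal_mapped_length": modal}
    try:
        pf = position_freq(surviving.subset(mapped), modal)
        pf.to_csv(out / f"position_freq_{modal}.tsv", sep="\t", index=False)
        manifest["stages"]["sizestats"]["five_prime_u"] = float(pf["U"].iloc[0])
    except ValueError:
        pass

    # -- strand balance / coverage / telomere profile ------------------------
    record_lengths = dict(zip(chr1.record_ids, chr1.record_lengths))
    rows = strand_count_table(hits, surviving.counts,
                              record_ids=chr1.record_ids, cfg=cfg.envelope)
    rows.to_csv(out / "strand_counts.tsv", sep="\t", index=False)
    strand_stats: dict = {"n_rows": len(rows)}
    if len(rows) >= 2:
        strand_stats["pearson_total"] = pearson_r(rows, "total")
        strand_stats["pearson_distinct"] = pearson_r(rows, "distinct")
        strand_stats["envelope_inside_frac"] = envelope_inside_fraction(
            rows["plus_total"], rows["minus_total"], cfg.envelope)
    if len(rows) >= 20:
        strand_stats["empirical_band"] = empirical_band(rows, "total",
                                                        cfg.envelope)
    cvs = cv_table(hits, surviving.counts, record_lengths)
    cvs.to_csv(out / "coverage_cv.tsv", sep="\t", index=False)
    if len(cvs):
        strand_stats["median_cv"] = float(cvs["cv"].median())
    chr1_ann = ann[ann["id"].isin(record_lengths)]
    try:
        prof = telomere_end_profile(hits, surviving.counts, record_lengths,
                                    chr1_ann, cfg.profile, strand="+")
        prof.binned().to_csv(out / "end_profile_plus.tsv", sep="\t",
                             index=False)
        strand_stats["depletion_fold"] = depletion_fold(prof)
    except ValueError:
        strand_stats["depletion_fold"] = None
    manifest["stages"]["strandprofile"] = strand_stats

    from . import __version__
    manifest["version"] = __version__
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
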