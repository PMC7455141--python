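"""End-to-end orchestration: simulate -> call -> annotate -> prim.

A run is described by a :class:`RunConfig` (YAML-loadable); every enabled
stage reads/writes standard formats (FASTA, FASTQ, GFF3, BED6, TSV) in the
output directory, the fully-resolved configuration is written beside the
outputs, and a machine-readable :class:`RunReport` (JSON) records per-stage
checksums, counts and wall times.  Identical configuration and seed give
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as pio
from . import junction_calling as jc
from . import prim_stats as ps
from .feature_annotation import summarize_categories
from .synthetic_data import (
    ReferenceGenome,
    SimulationConfig,
    generate_gene_model,
    generate_genome,
    generate_junction_reads,
    generate_random_ta_fragments,
    read_gff3,
    sb100x_transposon,
    simulate_integrations,
    write_gff3,
)

logger = logging.getLogger("primsite")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "call", "annotate", "prim")
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    genome_fasta: str | None = None
    genes_gff3: str | None = None
    reads_fastq: str | None = None
    sites_bed: str | None = None
    window_width: int = 20_000
    alpha: float = 0.05
    transposon_length: int = 32_400

    def __post_init__(self) -> None:
        known = {"simulate", "call", "annotate", "prim"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        # the seed propagates into every stochastic stage
        if self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = SimulationConfig(**d.pop("sim", {}))
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(sim=sim, **d)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["sim"]["chromosome_lengths"] = (
            list(self.sim.lengths)
            if not isinstance(self.sim.chromosome_lengths, int)
            else self.sim.chromosome_lengths
        )
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class RunReport:
    version: str
    seed: int
    stages: list[str]
    checksums: dict[str, str] = field(default_factory=dict)
    counts: dict[str, object] = field(default_factory=dict)
    rejections: dict[str, int] = field(default_factory=dict)
    category_summary: dict[str, float] = field(default_factory=dict)
    n_enriched_windows: int | None = None
    clonality: dict[str, float] = field(default_factory=dict)
    wall_time_s: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Input validation


@dataclass
class Finding:
    level: str  # "fatal" | "warning"
    message: str
    path: str | None = None
    line: int | None = None


def validate_inputs(config: RunConfig) -> list[Finding]:
    """Well-formedness and cross-file consistency checks on user inputs.

    FASTA bases must be A/C/G/T/N (N-containing regions are excluded from
    TA indexing with a logged count); BED coordinates must lie within
    their chromosome; GFF3 chromosomes must exist in the FASTA.
    """
    findings: list[Finding] = []
    genome: dict[str, str] | None = None
    if config.genome_fasta:
        p = Path(config.genome_fasta)
        if not p.exists():
            return [Finding("fatal", "genome FASTA does not exist", str(p))]
        genome = pio.read_fasta(p)
        for name, seq in genome.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                findings.append(
                    Finding("fatal", f"chromosome {name!r} has bases {sorted(bad)}", str(p))
                )
            n_count = seq.count("N")
            if n_count:
                logger.info("chromosome %s: %d N bases excluded from TA indexing",
                            name, n_count)
    if config.genes_gff3:
        p = Path(config.genes_gff3)
        if not p.exists():
            findings.append(Finding("fatal", "gene GFF3 does not exist", str(p)))
        else:
            model = read_gff3(p)
            for g in model.genes:
                if genome is not None:
                    if g.chromosome not in genome:
                        findings.append(Finding(
                            "fatal",
                            f"gene {g.gene_id} on chromosome {g.chromosome!r} "
                            "absent from FASTA", str(p)))
                    elif g.end > len(genome[g.chromosome]):
                        findings.append(Finding(
                            "fatal", f"gene {g.gene_id} exceeds chromosome bounds",
                            str(p)))
    if config.sites_bed:
        p = Path(config.sites_bed)
        if not p.exists():
            findings.append(Finding("fatal", "site BED does not exist", str(p)))
        else:
            with open(p) as fh:
                for lineno, line in enumerate(fh, 1):
                    if not line.strip() or line.startswith(("#", "track")):
                        continue
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) < 6:
                        findings.append(Finding("fatal", "BED line has < 6 columns",
                                                str(p), lineno))
                        continue
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    if genome is not None:
                        if chrom not in genome:
                            findings.append(Finding(
                                "fatal", f"BED chromosome {chrom!r} absent from FASTA",
                                str(p), lineno))
                        elif end > len(genome[chrom]):
                            findings.append(Finding(
                                "fatal", "BED interval beyond chromosome end",
                                str(p), lineno))
    if config.reads_fastq:
        p = Path(config.reads_fastq)
        if not p.exists():
            findings.append(Finding("fatal", "reads FASTQ does not exist", str(p)))
        else:
            try:
                pio.read_fastq(p)
            except Exception as exc:  # malformed FASTQ
                findings.append(Finding("fatal", f"FASTQ parse error: {exc}", str(p)))
    return findings


# ---------------------------------------------------------------------------
# The pipeline


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order and write all artifacts.

    Stage chain: ``simulate`` produces genome/genes/reads/truth files;
    ``call`` consumes reads+genome; ``annotate`` consumes sites+genes;
    ``prim`` consumes sites+genome (plus the randomized TA null).  Inputs
    not produced by an enabled stage must be provided as paths.  A stage
    failure aborts with the stage named; earlier outputs are kept.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log", config.seed)
    report = RunReport(
        version=__version__, seed=config.seed, stages=list(config.stages),
    )
    config.to_yaml(out / "config.resolved.yaml")
    report.config = yaml.safe_load((out / "config.resolved.yaml").read_text())

    findings = validate_inputs(config)
    fatal = [f for f in findings if f.level == "fatal"]
    if fatal:
        raise StageFailure("validate", ValueError(
            "; ".join(f"{f.path or ''}:{f.line or ''} {f.message}" for f in fatal)
        ))

    genome: ReferenceGenome | None = None
    model = None
    reads = None
    sites = None
    tp = sb100x_transposon(
        total_length=config.transposon_length, avoid_motif="GAGCTC"
    )

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        try:
            genome = generate_genome(config.sim)
            model = generate_gene_model(genome, config.sim)
            events = simulate_integrations(
                genome, config.sim.n_integrations,
                config.sim.hotspot_spec, seed=config.seed,
            )
            reads = generate_junction_reads(genome, events, tp, config.sim)
            pio.write_fasta(out / "genome.fa", genome.chromosomes, seed=config.seed)
            write_gff3(out / "genes.gff3", model, genome, seed=config.seed)
            pio.write_fastq(out / "reads.fq", reads, seed=config.seed)
            truth = _events_to_sites(events, config.sim.reads_per_event)
            pio.write_sites_bed(out / "truth.bed", truth, seed=config.seed)
            report.counts["simulated_events"] = len(events)
            report.counts["reads"] = len(reads)
        except Exception as exc:
            raise StageFailure("simulate", exc) from exc
        report.wall_time_s["simulate"] = round(time.perf_counter() - t0, 3)
    else:
        if config.genome_fasta:
            genome = ReferenceGenome(
                {k: v.replace("N", "") if "N" in v else v
                 for k, v in pio.read_fasta(config.genome_fasta).items()}
            )
        if config.genes_gff3:
            model = read_gff3(config.genes_gff3)
        if config.reads_fastq:
            reads = pio.read_fastq(config.reads_fastq)
        if config.sites_bed:
            sites = pio.read_sites_bed(config.sites_bed)
            sites["sample_id"] = "sample"

    if "call" in config.stages:
        t0 = time.perf_counter()
        try:
            if reads is None or genome is None:
                raise ValueError("call stage needs reads and a genome")
            params = jc.CallParams(end_match_length=config.sim.end_match_length)
            result = jc.call_unique_sites(reads, tp, genome, params)
            sites = result.sites
            pio.write_sites_bed(out / "sites.bed", sites, seed=config.seed)
            rej = {r: int(result.rejections.get(r, 0)) for r in jc.REJECT_REASONS}
            pio.write_tsv(
                out / "rejections.tsv",
                _dict_to_frame(rej, "reason", "count"),
            )
            report.rejections = rej
            report.counts["unique_sites"] = int(len(sites))
            report.counts["reads_in"] = result.n_reads
            if not sites.empty:
                clon = jc.compute_clonality(sites)
                report.clonality = {
                    "max_clone_fraction": clon.max_clone_fraction,
                    "shannon_entropy": clon.shannon_entropy,
                    "site_count": clon.site_count,
                }
        except Exception as exc:
            raise StageFailure("call", exc) from exc
        report.wall_time_s["call"] = round(time.perf_counter() - t0, 3)

    if "annotate" in config.stages:
        t0 = time.perf_counter()
        try:
            if sites is None or model is None:
                raise ValueError("annotate stage needs sites and a gene model")
            if sites.empty:
                logger.warning("no sites to annotate")
            else:
                summary = summarize_categories(sites, model)
                pio.write_tsv(out / "categories.tsv", summary.to_frame())
                report.category_summary = {
                    k: round(v, 4) for k, v in summary.percentages.items()
                }
        except Exception as exc:
            raise StageFailure("annotate", exc) from exc
        report.wall_time_s["annotate"] = round(time.perf_counter() - t0, 3)

    if "prim" in config.stages:
        t0 = time.perf_counter()
        try:
            if sites is None or genome is None:
                raise ValueError("prim stage needs sites and a genome")
            windows = ps.build_windows(genome, config.window_width)
            windows = ps.assign_observed(windows, sites)
            fit = ps.fit_prim(windows)
            tested = ps.test_windows(windows, fit, alpha=config.alpha)
            pio.write_tsv(out / "windows.tsv", tested)
            hist = ps.occupancy_histogram(windows)
            pio.write_tsv(out / "occupancy.tsv",
                          _dict_to_frame(hist, "insertions", "windows"))
            n_frag = config.sim.n_random_fragments or config.sim.n_integrations
            frags = generate_random_ta_fragments(
                genome, n_frag, config.sim.random_fragment_length,
                seed=config.seed,
            )
            rand_sites = jc.map_random_fragments(frags, genome)
            if not rand_sites.empty and not sites.empty:
                comp = ps.compare_random_null(sites, rand_sites, windows)
                pio.write_tsv(out / "null_comparison.tsv", comp.per_chromosome)
                report.counts["null_chi_square_p"] = comp.p_value
            report.n_enriched_windows = int(tested["enriched"].sum())
            report.counts["tested_windows"] = int(tested["tested"].sum())
            report.counts["max_window_occupancy"] = max(hist) if hist else 0
        except Exception as exc:
            raise StageFailure("prim", exc) from exc
        report.wall_time_s["prim"] = round(time.perf_counter() - t0, 3)

    for f in sorted(out.iterdir()):
        if f.name == "config.resolved.yaml":
            continue  # embeds the output path; not a data artifact
        if f.is_file() and f.suffix in {".fa", ".fq", ".gff3", ".bed", ".tsv", ".yaml"}:
            report.checksums[f.name] = _sha256(f)
    report.to_json(out / "report.json")
    return report


def _events_to_sites(events, reads_per_event: int):
    import pandas as pd

    rows = [
        {
            "chromosome": e.chromosome,
            "position": e.position,
            "orientation": e.orientation,
            "support_reads": 2 * reads_per_event,
            "site_id": e.event_id,
        }
        for e in events
    ]
    df = pd.DataFrame(
        rows, columns=["chromosome", "position", "orientation",
                       "support_reads", "site_id"],
    )
    return df.sort_values(["chromosome", "position"], kind="stable").reset_index(
        drop=True
    )


def _dict_to_frame(d: dict, key: str, value: str):
    import pandas as pd

    return pd.DataFrame({key: list(d.keys()), value: list(d.values())})


def _setup_logging(logfile: Path, seed: int) -> None:
    root = logging.getLogger("primsite")
    root.setLevel(logging.INFO)
    have = {getattr(h, "_primsite_tag", None) for h in root.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
        h._primsite_tag = "stderr"
        root.addHandler(h)
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s [%(name)s] %(levelname)s %(message)s"))
    fh._primsite_tag = "file"
    for h in [h for h in root.handlers if getattr(h, "_primsite_tag", None) == "file"]:
        root.removeHandler(h)
    root.addHandler(fh)
    logger.info("primsite %s, seed %d", __version__, seed)
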