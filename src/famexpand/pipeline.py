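"""Pipeline orchestration and the `famexpand` command-line interface.

Subcommands map one-to-one onto the library modules: `simulate` writes a
synthetic bundle, `metrics` computes assembly statistics and OHR tables,
`census` runs the gene-family census, and `recover` runs the census and
scores it against a generator truth file, printing the exact-match fraction
as its final line. All tables are TSV with header rows; the ">=" display of
minimum gene counts lives in a separate column so numeric columns stay
machine-readable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path
from typing import Dict, List, Optional

import click
import pandas as pd

from . import __version__, assembly_metrics, seqio
from .family_census import CensusConfig, ProteinRecord, census
from .synthetic_data import (GeneratorConfig, SyntheticTruth, TruthRow,
                             generate, score_recovery)
from .translated_search import search

log = logging.getLogger("famexpand")


@dataclasses.dataclass
class PipelineConfig:
    transcripts: str = ""
    proteome: str = ""
    annotation: str = ""
    hit_table: Optional[str] = None
    reads: Optional[str] = None
    # name -> protein FASTA path; enables the multi-reference hit partition
    extra_proteomes: Optional[Dict[str, str]] = None
    out_dir: str = "famexpand_out"
    seed: int = 0
    e_max: float = 1e-3
    contig_min: int = 150
    census_min: int = 250
    isoform_identity: float = 0.95
    isoform_coverage: float = 0.80
    min_overlap: int = 15
    overlap_frac: float = 0.10

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def census_config(self) -> CensusConfig:
        return CensusConfig(
            e_max=self.e_max, census_min_len=self.census_min,
            isoform_identity=self.isoform_identity,
            isoform_coverage=self.isoform_coverage,
            min_overlap=self.min_overlap, overlap_frac=self.overlap_frac)


def read_annotation(path) -> Dict[str, Dict[str, str]]:
    """Annotation TSV: protein_id, family, clan, description."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"protein_id", "family", "clan", "description"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    return {r.protein_id: {"family": r.family, "clan": r.clan,
                           "description": r.description}
            for r in df.itertuples()}


def load_proteome(fasta_path, annotation_path) -> List[ProteinRecord]:
    ann = read_annotation(annotation_path)
    records = seqio.read_fasta(fasta_path, molecule="aa")
    out = []
    for rec in records:
        meta = ann.get(rec.id)
        if meta is None:
            raise KeyError(f"protein {rec.id!r} missing from annotation table")
        out.append(ProteinRecord(id=rec.id, seq=rec.seq,
                                 family=meta["family"], clan=meta["clan"],
                                 description=meta["description"]))
    return out


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute metrics + census and write the report bundle.

    Writes assembly_summary.tsv, ohr_table.tsv, ohr_summary.tsv,
    family_counts.tsv, cluster_ledger.tsv and manifest.json under
    config.out_dir; returns the manifest dict.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: Dict[str, float] = {}

    transcripts = seqio.read_fasta(config.transcripts, molecule="nt")
    transcripts = seqio.filter_contigs(transcripts, config.contig_min)
    proteome = load_proteome(config.proteome, config.annotation)
    stage_times["load"] = time.time() - t0

    t1 = time.time()
    summary = assembly_metrics.assembly_summary(
        [len(t.seq) for t in transcripts])
    hist = summary.pop("histogram")
    edges = summary.pop("histogram_edges")
    srow = dict(summary)
    labels = ([f"<{edges[0]}"]
              + [f"{a}-{b - 1}" for a, b in zip(edges, edges[1:])]
              + [f">={edges[-1]}"])
    for lab, c in zip(labels, hist):
        srow[f"len_{lab}"] = c
    pd.DataFrame([srow]).to_csv(out / "assembly_summary.tsv", sep="\t",
                                index=False)

    hits = None
    if config.hit_table:
        hits = seqio.read_hit_table(
            config.hit_table, {t.id: len(t.seq) for t in transcripts})
        top = {}
        from .translated_search import top_hits_from
        top = top_hits_from([h for h in hits if h.e_value <= config.e_max])
    else:
        prot_seqs = [seqio.SequenceRecord(id=p.id, seq=p.seq)
                     for p in proteome]
        hits, top = search(transcripts, prot_seqs, e_max=config.e_max)
    stage_times["search"] = time.time() - t1

    t2 = time.time()
    ohr_records = assembly_metrics.ohr_table(top, proteome)
    pd.DataFrame([dataclasses.asdict(r) for r in ohr_records]).to_csv(
        out / "ohr_table.tsv", sep="\t", index=False)
    summary_ohr = assembly_metrics.ohr_summary(ohr_records)
    pd.DataFrame([{f"frac_gt_{t}": v for t, v in summary_ohr.items()}]).to_csv(
        out / "ohr_summary.tsv", sep="\t", index=False)
    if config.extra_proteomes:
        hit_sets = {"main": set(top)}
        for name, fasta in sorted(config.extra_proteomes.items()):
            extra_db = [seqio.SequenceRecord(id=r.id, seq=r.seq)
                        for r in seqio.read_fasta(fasta, molecule="aa")]
            _, extra_top = search(transcripts, extra_db, e_max=config.e_max)
            hit_sets[name] = set(extra_top)
        table = assembly_metrics.hit_partition(hit_sets)
        table.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
    stage_times["metrics"] = time.time() - t2

    t3 = time.time()
    result = census(transcripts, proteome, hits=hits,
                    config=config.census_config())
    result.counts_frame().to_csv(out / "family_counts.tsv", sep="\t",
                                 index=False)
    result.ledger.to_csv(out / "cluster_ledger.tsv", sep="\t", index=False)
    stage_times["census"] = time.time() - t3

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "n_transcripts": len(transcripts),
        "n_proteins": len(proteome),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_simulation(dataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqio.write_fasta(
        [seqio.SequenceRecord(id=p.id, seq=p.seq, description=p.description)
         for p in dataset.proteome], out / "proteome.faa")
    pd.DataFrame(
        [{"protein_id": p.id, "family": p.family, "clan": p.clan,
          "description": p.description} for p in dataset.proteome]
    ).to_csv(out / "annotation.tsv", sep="\t", index=False)
    seqio.write_fasta(dataset.transcripts, out / "transcripts.fna")
    pd.DataFrame([dataclasses.asdict(r) for r in dataset.truth.rows]).to_csv(
        out / "truth.tsv", sep="\t", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(dataset.config), fh, indent=2,
                  sort_keys=True)


def read_truth(path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rows = [TruthRow(transcript_id=r.transcript_id,
                     true_gene_id=r.true_gene_id,
                     true_family=r.true_family, role=r.role)
            for r in df.itertuples()]
    counts: Dict[str, int] = {}
    for gid, fam in {(r.true_gene_id, r.true_family)
                     for r in rows if r.role != "junk"}:
        counts[fam] = counts.get(fam, 0) + 1
    return SyntheticTruth(rows=rows, family_gene_counts=counts)


def _config_from_options(**kw) -> PipelineConfig:
    cfg_path = kw.pop("config", None)
    cfg = PipelineConfig.from_json(cfg_path) if cfg_path else PipelineConfig()
    for key, value in kw.items():
        if value is not None:
            setattr(cfg, key, value)
    return cfg


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Gene-family census and assembly metrics for de novo transcriptomes."""
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO,
        format="[famexpand:%(levelname)s] %(message)s")


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(), default="sim_out",
              show_default=True)
@click.option("--n-families", type=int, default=20, show_default=True)
@click.option("--fragment-prob", type=float, default=0.5, show_default=True)
@click.option("--isoform-prob", type=float, default=0.2, show_default=True)
@click.option("--base-error-rate", type=float, default=0.0, show_default=True)
def simulate(seed, out_dir, n_families, fragment_prob, isoform_prob,
             base_error_rate) -> None:
    """Generate a synthetic proteome/assembly bundle with truth ledger."""
    cfg = GeneratorConfig(seed=seed, n_families=n_families,
                          fragment_prob=fragment_prob,
                          isoform_prob=isoform_prob,
                          base_error_rate=base_error_rate)
    dataset = generate(cfg)
    write_simulation(dataset, out_dir)
    log.info("wrote simulation bundle to %s", out_dir)


def _common_options(fn):
    fn = click.option("--config", type=click.Path(exists=True))(fn)
    fn = click.option("--transcripts", type=click.Path(exists=True))(fn)
    fn = click.option("--proteome", type=click.Path(exists=True))(fn)
    fn = click.option("--annotation", type=click.Path(exists=True))(fn)
    fn = click.option("--hit-table", type=click.Path(exists=True))(fn)
    fn = click.option("--out-dir", type=click.Path())(fn)
    fn = click.option("--e-max", type=float)(fn)
    fn = click.option("--min-overlap", type=int)(fn)
    fn = click.option("--census-min", type=int)(fn)
    return fn


@cli.command()
@_common_options
def metrics(**kw) -> None:
    """Assembly summary, OHR table/summary (runs the full pipeline)."""
    cfg = _config_from_options(**kw)
    run_pipeline(cfg)


@cli.command(name="census")
@_common_options
def census_cmd(**kw) -> None:
    """Run the gene-family census and write counts + cluster ledger."""
    cfg = _config_from_options(**kw)
    manifest = run_pipeline(cfg)
    log.info("census finished in %.1fs",
             manifest["stage_seconds"].get("census", 0.0))


@cli.command()
@click.option("--truth", type=click.Path(exists=True), required=True)
@_common_options
def recover(truth, **kw) -> None:
    """Census plus truth comparison; prints the exact-match fraction last."""
    cfg = _config_from_options(**kw)
    run_pipeline(cfg)
    transcripts = seqio.read_fasta(cfg.transcripts, molecule="nt")
    transcripts = seqio.filter_contigs(transcripts, cfg.contig_min)
    proteome = load_proteome(cfg.proteome, cfg.annotation)
    hits = None
    if cfg.hit_table:
        hits = seqio.read_hit_table(cfg.hit_table,
                                    {t.id: len(t.seq) for t in transcripts})
    result = census(transcripts, proteome, hits=hits,
                    config=cfg.census_config())
    report = score_recovery(result, read_truth(truth))
    for fam, t, e, ok in report.per_family:
        log.info("family %s: true %d, estimated %d%s", fam, t, e,
                 "" if ok else " (MISMATCH)")
    click.echo(f"{report.exact_match_fraction:.3f}")


def main() -> None:
    cli(standalone_mode=True)


if __name__ == "__main__":
    main()
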