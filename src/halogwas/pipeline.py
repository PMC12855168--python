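"""End-to-end orchestration: phenotype -> GWAS -> mapping -> report.

Every stage writes its outputs before the next begins, and every output is a
pure function of the inputs plus the run configuration (no timestamps inside
output files), so a re-run over the same inputs is byte-identical and any
stage can be re-run standalone from the previous stage's files.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, io, phenotyping
from .association import GwasConfig, run_gwas
from .kmers import GenomePanel, encode_kmer


@dataclass
class RunConfig:
    genomes_manifest: str
    out_dir: str
    phenotype_path: str | None = None
    readings_path: str | None = None  # long kinetic readings, alternative
    areas_path: str | None = None     # precomputed AOU table, alternative
    gff_manifest: str | None = None
    pangenome_path: str | None = None
    replicon_manifest: str | None = None
    control_condition: float = 0.0
    salt_condition: float = 600.0
    k: int = 13
    min_present: int = 2
    min_absent: int = 2
    alpha: float = 0.05
    correct_structure: bool = True
    top_p: float | None = None
    top_n: int | None = None
    promoter_window: int = 600
    pm_threshold: float = 13000.0
    seed: int = 0


def _log(msg: str) -> None:
    stamp = time.strftime("%Y-%m-%d %H:%M:%S")
    print(f"[{stamp}] {msg}", file=sys.stderr)


def run_all(cfg: RunConfig, log=_log) -> dict:
    """Execute the full chain and return the report summary dict.

    Fails fast (ValueError) when genomes and phenotype share no strains,
    naming the offending inputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log(f"loading genomes from {cfg.genomes_manifest}")
    panel = io.read_genome_manifest(cfg.genomes_manifest)

    # --- phenotype stage -------------------------------------------------
    if cfg.phenotype_path:
        phenotype = io.read_phenotype(cfg.phenotype_path)
    elif cfg.readings_path or cfg.areas_path:
        if cfg.readings_path:
            readings = pd.read_csv(cfg.readings_path, sep="\t")
            areas = phenotyping.areas_from_readings(readings)
        else:
            areas = pd.read_csv(cfg.areas_path, sep="\t")
        normalized = phenotyping.normalize_activity(
            areas, control_condition=cfg.control_condition)
        io.write_tsv(out / "normalized_activity.tsv",
                     normalized.drop(columns=["replicate_ratios"]))
        io.write_tsv(out / "tolerance_profile.tsv",
                     phenotyping.tolerance_profile(normalized))
        sub = normalized[normalized["condition"] == cfg.salt_condition]
        phenotype = dict(zip(sub["strain"], sub["mean_ratio"]))
    else:
        raise ValueError("one of phenotype_path, readings_path or "
                         "areas_path is required")
    overlap = [s for s in panel.strain_ids if s in phenotype]
    if not overlap:
        missing = sorted(set(panel.strain_ids) - set(phenotype))
        raise ValueError("no strain overlap between genomes and phenotype; "
                         f"genome strains without phenotype: {missing}")
    log(f"phenotype covers {len(overlap)}/{len(panel.strain_ids)} strains")

    # --- GWAS stage ------------------------------------------------------
    gwas_cfg = GwasConfig(k=cfg.k, min_present=cfg.min_present,
                          min_absent=cfg.min_absent, alpha=cfg.alpha,
                          correct_structure=cfg.correct_structure)
    result = run_gwas(panel, phenotype, gwas_cfg, log=log)
    io.write_tsv(out / "associations.tsv", result.associations)
    if result.weights is not None:
        wdf = pd.DataFrame({
            "strain_id": sorted(result.weights.weights),
            "weight": [result.weights.weights[s]
                       for s in sorted(result.weights.weights)]})
        io.write_tsv(out / "structure_weights.tsv", wdf)
        (out / "guide_tree.nwk").write_text(
            result.weights.tree.as_string(schema="newick"))

    top = result.top(top_p=cfg.top_p, top_n=cfg.top_n)
    sig_kmers = list(top["kmer"])
    log(f"mapping {len(sig_kmers)} significant k-mers")

    # --- mapping stage ---------------------------------------------------
    hit_tables = []
    summary_counts = {}
    if cfg.gff_manifest and sig_kmers:
        annotations = io.read_gff_manifest(cfg.gff_manifest)
        for strain, scaffolds in panel.entries:
            cds = annotations.get(strain)
            if cds is None:
                continue
            present = set(result.matrix.strain_kmer_codes(strain).tolist())
            strain_kmers = [km for km in sig_kmers
                            if min(encode_kmer(km),
                                   encode_kmer(
                                       annotate.reverse_complement(km)))
                            in present]
            if not strain_kmers:
                continue
            placements = annotate.locate_kmers_indexed(strain_kmers,
                                                       scaffolds)
            hits = annotate.classify_hits(placements, cds,
                                          window=cfg.promoter_window)
            hits.insert(0, "strain", strain)
            hit_tables.append(hits)
        hits_all = (pd.concat(hit_tables, ignore_index=True)
                    if hit_tables else annotate.classify_hits([], []))
        if "strain" not in hits_all.columns:
            hits_all.insert(0, "strain", [])
        io.write_tsv(out / "kmer_hits.tsv", hits_all)
        summary_counts = annotate.hit_summary(hits_all)
        reg = hits_all[hits_all["hit_class"] == "regulatory"]
        io.write_tsv(out / "regulatory_hits.tsv", reg)
        tally = annotate.cog_tally(hits_all,
                                   strain_of=lambda row: row["strain"])
        tally.index.name = "cog_class"
        tally.reset_index().to_csv(out / "cog_tally.tsv", sep="\t",
                                   index=False)
        if cfg.pangenome_path:
            pa = io.read_roary_matrix(cfg.pangenome_path)
            gene_loci = hits_all.loc[hits_all["hit_class"] == "gene",
                                     "locus"].dropna().unique()
            matches, unmatched = annotate.match_to_pangenome(gene_loci, pa)
            rows = [{"locus": locus, **info}
                    for locus, info in sorted(matches.items())]
            rows += [{"locus": locus, "cluster": "unmatched",
                      "n_strains": 0, "strain_unique": False}
                     for locus in sorted(unmatched)]
            io.write_tsv(out / "pangenome_matches.tsv", pd.DataFrame(rows))
        log(f"hit summary: {summary_counts}")

    # --- report ----------------------------------------------------------
    report = {
        "n_strains": len(panel.strain_ids),
        "n_kmers_total": result.n_kmers_total,
        "n_kmers_tested": result.n_kmers_tested,
        "n_kmers_significant": int(
            (result.associations["p"] <= cfg.alpha).sum()),
        "n_kmers_mapped": len(sig_kmers),
        **summary_counts,
    }
    manifest = {"config": asdict(cfg), "report": report}
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    lines = [f"{key}\t{value}" for key, value in report.items()]
    (out / "report.tsv").write_text("\n".join(lines) + "\n")
    log("run complete")
    return report
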