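"""Full pipeline run on a generated fixture directory.

Writes a synthetic panel (FASTA + GFF3 + phenotype TSV) to a temporary
directory, then drives phenotype -> GWAS -> mapping -> report through the
same orchestration layer the `halogwas run-all` command uses. The report
counts significant k-mers and the genes/promoter regions they pinpoint.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

import halogwas as h
from halogwas.io import write_genome_panel, write_gff3_cds, write_phenotype
from halogwas.pipeline import RunConfig, run_all

cfg = h.SimulationConfig(n_strains=14, backbone_length=12_000,
                         n_accessory_genes=5, n_causal=2,
                         effect_sizes=[0.3, 0.3], noise_sd=0.02, seed=8)
panel, annotations, truth = h.simulate_panel(cfg)
phenotype, _ = h.simulate_phenotype(truth, cfg)

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    write_genome_panel(panel, root / "genomes")
    (root / "gff").mkdir()
    rows = []
    for strain, cds in annotations.items():
        write_gff3_cds(root / "gff" / f"{strain}.gff3", cds)
        rows.append({"strain_id": strain, "gff_path": f"{strain}.gff3"})
    pd.DataFrame(rows).to_csv(root / "gff" / "manifest.tsv", sep="\t",
                              index=False)
    write_phenotype(root / "phenotype.tsv", phenotype)

    report = run_all(RunConfig(
        genomes_manifest=str(root / "genomes" / "manifest.tsv"),
        phenotype_path=str(root / "phenotype.tsv"),
        gff_manifest=str(root / "gff" / "manifest.tsv"),
        out_dir=str(root / "out"), salt_condition=600.0))

    print("\nreport:", json.dumps(report, indent=2))
    hits = pd.read_csv(root / "out" / "kmer_hits.tsv", sep="\t")
    gene_hits = hits[hits["hit_class"] == "gene"]["locus"].dropna()
    tagged_genes = {locus.split("_", 1)[1] for locus in gene_hits}
    planted = {gid for gid, _, _ in truth.causal_loci}
    print(f"planted causal genes: {sorted(planted)}")
    print(f"genes reached by significant k-mers include them: "
          f"{planted <= tagged_genes}")
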