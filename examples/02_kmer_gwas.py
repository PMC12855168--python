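"""k-mer GWAS walk-through on a synthetic panel with planted causal genes.

Simulates 30 draft genomes sharing a backbone (segregating SNPs plus
accessory genes), gives carriers of one accessory gene a salt-tolerance
deficit of three noise standard deviations, and runs the full chain:
canonical 13-mer counting, min-2/max-2 filtering, GSC clonal-structure
weights from a UPGMA guide tree, and the weighted Welch t-test per k-mer.
"""

import halogwas as h
from halogwas.kmers import count_kmers

cfg = h.SimulationConfig(n_strains=30, backbone_length=30_000,
                         n_accessory_genes=6, n_causal=1,
                         effect_sizes=[0.15], noise_sd=0.05, seed=3)
panel, annotations, truth = h.simulate_panel(cfg)
phenotype, _ = h.simulate_phenotype(truth, cfg)

result = h.run_gwas(panel, phenotype, h.GwasConfig(k=13), log=print)

assoc = result.associations
print(f"\n{len(assoc)} k-mers significant at p <= 0.05; top of the table:")
print(assoc.head(5).to_string(index=False))

causal_kmers = set()
for gene_id, seq, effect in truth.causal_loci:
    causal_kmers |= count_kmers([seq], 13)
top_p = assoc["p"].min()
top = set(assoc.loc[assoc["p"] <= top_p * (1 + 1e-9), "kmer"])
print(f"\nminimum p-value stratum: {len(top)} k-mers, "
      f"{len(top & causal_kmers)} of them from the planted causal gene")
print("The causal gene's k-mers occupy the extreme-p stratum because "
      "their presence pattern tracks the phenotype shift; background SNP "
      "k-mers reach the significance threshold only by chance or by "
      "co-occurring with the causal carriage.")
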