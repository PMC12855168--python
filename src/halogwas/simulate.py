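"""Truth-labelled synthetic strain panels for end-to-end pipeline testing.

The generator emulates what the pipeline assumes about a real panel of draft
genomes: a shared backbone with strain-specific SNPs, accessory ORF-like
genes present in a subset of strains, optional clone groups of near-identical
strains, a continuous phenotype in [0, 1] driven additively by a subset of
accessory genes (carriers lose activity), replicate kinetic areas whose
normalization recovers that phenotype, and PM-style carbon-source areas with
designated tolerant/sensitive strains. Everything is deterministic given the
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import CdsRecord
from .kmers import GenomePanel
from .phenotyping import KineticCurve

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    n_strains: int = 30
    backbone_length: int = 50_000
    snp_rate: float = 0.01  # per-site probability of segregating in the panel
    n_accessory_genes: int = 10
    accessory_prevalence: float = 0.5
    n_causal: int = 5
    effect_sizes: list | None = None  # default: 1.5 * noise_sd per locus
    noise_sd: float = 0.03
    baseline: float = 0.9
    n_replicates: int = 3
    control_aou_scale: float = 50_000.0
    aou_cv: float = 0.03  # replicate-level coefficient of variation
    n_core_genes: int = 8
    n_clone_pairs: int = 0
    n_scaffolds: int = 1
    salt_condition: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.accessory_prevalence <= 1):
            raise ValueError("accessory_prevalence must be in [0, 1]")
        if self.n_causal > self.n_accessory_genes:
            raise ValueError("n_causal cannot exceed n_accessory_genes")
        if self.snp_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates must be non-negative")

    def resolved_effects(self) -> np.ndarray:
        if self.effect_sizes is not None:
            if len(self.effect_sizes) != self.n_causal:
                raise ValueError("effect_sizes length must equal n_causal")
            return np.asarray(self.effect_sizes, float)
        return np.full(self.n_causal, 1.5 * self.noise_sd)


@dataclass
class GroundTruth:
    causal_loci: list  # (gene_id, inserted sequence, effect)
    carriers: dict  # gene_id -> sorted list of carrier strain_ids
    insert_positions: dict  # gene_id -> backbone offset of insertion
    clone_groups: list  # partition of strain_ids
    strain_phenotypes: dict = field(default_factory=dict)  # latent values
    n_clipped: int = 0


def _random_seq(rng, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _random_orf(rng, min_len=300, max_len=1500) -> str:
    """ORF-like block: ATG, random non-stop codons, a stop codon."""
    n_codons = int(rng.integers(min_len // 3, max_len // 3 + 1))
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons - 2:
        c = _random_seq(rng, 3)
        if c not in stops and c != "ATG":
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def simulate_panel(cfg: SimulationConfig):
    """Genomes + annotations + ground truth for one synthetic panel.

    Returns (GenomePanel, annotations, truth) where ``annotations`` maps
    strain_id -> list of CdsRecord. Clone pairs (when requested) copy both
    the SNP set and the accessory carriage of their parent strain, so the
    pair is genomically near-identical.
    """
    rng = np.random.default_rng(cfg.seed)
    strains = [f"S{i:03d}" for i in range(cfg.n_strains)]
    backbone = _random_seq(rng, cfg.backbone_length)

    # accessory genes and their fixed insertion sites on the backbone
    genes = {f"acc{g:03d}": _random_orf(rng)
             for g in range(cfg.n_accessory_genes)}
    gene_ids = sorted(genes)

    # core genes: fixed windows on the backbone, annotated in every strain
    core_coords = []
    if cfg.n_core_genes:
        spacing = cfg.backbone_length // (cfg.n_core_genes + 1)
        core_len = min(900, max(150, spacing // 2))
        for c in range(cfg.n_core_genes):
            start = (c + 1) * spacing - core_len // 2
            core_coords.append((f"core{c:03d}", start,
                                min(start + core_len - 1,
                                    cfg.backbone_length - 1)))

    # accessory insertion sites: outside core-gene windows, away from ends
    margin = min(2000, max(50, cfg.backbone_length // 20))
    allowed = np.ones(cfg.backbone_length, dtype=bool)
    allowed[:margin] = allowed[-margin:] = False
    for _, cstart, cend in core_coords:
        allowed[max(cstart - 50, 0):cend + 51] = False
    n_sites = cfg.n_accessory_genes
    sites = np.sort(rng.choice(np.flatnonzero(allowed), size=n_sites,
                               replace=False)) if n_sites \
        else np.empty(0, int)
    insert_positions = {gid: int(sites[i]) for i, gid in enumerate(gene_ids)}

    # accessory carriage per strain
    carriage = rng.random((cfg.n_strains, cfg.n_accessory_genes)) \
        < cfg.accessory_prevalence

    # SNPs segregate at panel level: each site polymorphic with probability
    # snp_rate; its derived allele is carried by a Binomial(f) strain subset
    # (a shared variant pool, as in a panel with common ancestry, rather
    # than private mutations that the min-2/max-2 filter would discard)
    seg_pos = np.flatnonzero(rng.random(cfg.backbone_length) < cfg.snp_rate)
    seg_shift = rng.integers(1, 4, size=seg_pos.size)
    freqs = rng.uniform(0.05, 0.95, size=seg_pos.size)
    snp_carrier = rng.random((cfg.n_strains, seg_pos.size)) < freqs
    snp_sets = [(seg_pos[snp_carrier[i]], seg_shift[snp_carrier[i]])
                for i in range(cfg.n_strains)]

    clone_groups = [[s] for s in strains]
    for p in range(cfg.n_clone_pairs):
        parent, clone = p, cfg.n_strains - 1 - p
        if clone <= parent:
            break
        carriage[clone] = carriage[parent]
        snp_sets[clone] = snp_sets[parent]
        clone_groups[parent].append(strains[clone])
        clone_groups[clone] = []
    clone_groups = [g for g in clone_groups if g]

    causal_ids = gene_ids[:cfg.n_causal]
    effects = cfg.resolved_effects()
    truth = GroundTruth(
        causal_loci=[(gid, genes[gid], float(effects[j]))
                     for j, gid in enumerate(causal_ids)],
        carriers={gid: [strains[i] for i in range(cfg.n_strains)
                        if carriage[i, gene_ids.index(gid)]]
                  for gid in gene_ids},
        insert_positions=insert_positions,
        clone_groups=clone_groups,
    )

    backbone_codes = np.frombuffer(backbone.encode(), dtype=np.uint8).copy()
    base_index = np.zeros(256, dtype=np.uint8)
    for bi, bb in enumerate(b"ACGT"):
        base_index[bb] = bi

    entries, annotations = [], {}
    for i, strain in enumerate(strains):
        codes = backbone_codes.copy()
        pos, shift = snp_sets[i]
        if pos.size:
            codes[pos] = _BASES[(base_index[codes[pos]] + shift) % 4]
        mutated = codes.tobytes().decode()
        # splice carried inserts left-to-right, tracking coordinate offsets
        pieces, cds = [], []
        cursor, offset = 0, 0
        carried = [(insert_positions[gid], gid) for gi, gid in
                   enumerate(gene_ids) if carriage[i, gi]]
        for site, gid in sorted(carried):
            pieces.append(mutated[cursor:site])
            seq = genes[gid]
            start = site + offset + 1  # 1-based
            cds.append(CdsRecord("sc1", start, start + len(seq) - 1, "+",
                                 locus_id=f"{strain}_{gid}",
                                 product=f"accessory protein {gid}",
                                 cog_class="G"))
            pieces.append(seq)
            offset += len(seq)
            cursor = site
        pieces.append(mutated[cursor:])
        genome = "".join(pieces)

        for cid, cstart, cend in core_coords:
            shift_by = sum(len(genes[gid]) for site, gid in carried
                           if site <= cstart)
            cds.append(CdsRecord("sc1", cstart + shift_by + 1,
                                 cend + shift_by + 1, "+",
                                 locus_id=f"{strain}_{cid}",
                                 product=f"core protein {cid}",
                                 cog_class="K"))
        cds.sort(key=lambda c: c.start)
        scaffolds, cds = _split_scaffolds(genome, cds, cfg.n_scaffolds,
                                          strain)
        entries.append((strain, scaffolds))
        annotations[strain] = cds

    return GenomePanel(entries), annotations, truth


def _split_scaffolds(genome: str, cds: list, n_scaffolds: int, strain: str):
    """Split a genome into scaffolds at positions outside every CDS."""
    if n_scaffolds <= 1:
        sid = f"{strain}_sc1"
        scaffolds = [(sid, genome)]
        renamed = [CdsRecord(sid, c.start, c.end, c.strand, c.locus_id,
                             c.product, c.cog_id, c.cog_class) for c in cds]
        return scaffolds, renamed
    length = len(genome)
    occupied = np.zeros(length + 2, dtype=bool)
    for c in cds:
        occupied[c.start:c.end + 1] = True
    targets = [length * (s + 1) // n_scaffolds for s in range(n_scaffolds - 1)]
    cuts = []
    for t in targets:
        p = t
        while p < length and occupied[p + 1]:
            p += 1
        if p < length and (not cuts or p > cuts[-1]):
            cuts.append(p)
    bounds = [0] + cuts + [length]
    scaffolds, new_cds = [], []
    for s in range(len(bounds) - 1):
        lo, hi = bounds[s], bounds[s + 1]
        sid = f"{strain}_sc{s + 1}"
        scaffolds.append((sid, genome[lo:hi]))
        for c in cds:
            if lo < c.start and c.end <= hi:
                new_cds.append(CdsRecord(sid, c.start - lo, c.end - lo,
                                         c.strand, c.locus_id, c.product,
                                         c.cog_id, c.cog_class))
    return scaffolds, new_cds


def simulate_phenotype(truth: GroundTruth, cfg: SimulationConfig,
                       strains: list | None = None):
    """Latent phenotypes plus a replicate AOU table that recovers them.

    latent_i = baseline - sum_j effect_j * carries_ij + N(0, noise_sd),
    clipped to [0, 1]. Control-condition AOUs are drawn around a fixed
    instrument scale; salt-condition AOUs equal latent x control scale with
    replicate noise, so that area normalization returns the latent value up
    to replicate noise. Returns (phenotype dict, AOU DataFrame); the latents
    are also stored in ``truth.strain_phenotypes``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if strains is None:
        strains = sorted({s for lst in truth.carriers.values() for s in lst}
                         | {f"S{i:03d}" for i in range(cfg.n_strains)})
    latent = {}
    n_clipped = 0
    for strain in strains:
        value = cfg.baseline
        for gid, _, effect in truth.causal_loci:
            if strain in truth.carriers[gid]:
                value -= effect
        value += rng.normal(0.0, cfg.noise_sd)
        clipped = min(max(value, 0.0), 1.0)
        if clipped != value:
            n_clipped += 1
        latent[strain] = clipped
    if n_clipped:
        warnings.warn(f"{n_clipped} phenotype values clipped to [0, 1]")
    truth.strain_phenotypes = dict(latent)
    truth.n_clipped = n_clipped

    rows = []
    scale = cfg.control_aou_scale
    for strain in strains:
        for rep in range(1, cfg.n_replicates + 1):
            rows.append({"strain": strain, "condition": 0.0,
                         "replicate": rep,
                         "aou": scale * (1 + rng.normal(0, cfg.aou_cv))})
            rows.append({"strain": strain, "condition": cfg.salt_condition,
                         "replicate": rep,
                         "aou": max(latent[strain] * scale
                                    * (1 + rng.normal(0, cfg.aou_cv)), 0.0)})
    return latent, pd.DataFrame(rows)


def kinetic_curve_for_area(strain: str, condition: str, replicate: int,
                           area: float, rng, t_max: float = 96.0,
                           t_step: float = 1.0) -> KineticCurve:
    """Logistic respiration curve whose trapezoidal area equals ``area``."""
    times = np.arange(0.0, t_max + 1e-9, t_step)
    midpoint = rng.uniform(20.0, 50.0)
    slope = rng.uniform(3.0, 8.0)
    shape = 1.0 / (1.0 + np.exp(-(times - midpoint) / slope))
    shape -= shape[0]
    raw = np.trapezoid(shape, times)
    signals = shape * (area / raw) if raw > 0 else np.zeros_like(times)
    return KineticCurve(strain, condition, replicate, times, signals)


def simulate_pm(strains_tolerant: list, strains_sensitive: list,
                n_substrates: int = 190, p_active: float = 0.55,
                retention_tolerant: float = 0.6,
                retention_sensitive: float = 0.45,
                threshold: float = 13000.0, seed: int = 0):
    """PM-style area tables with known active/retained substrate sets.

    Control-active wells draw areas well above ``threshold``; under salt a
    retained well keeps >= 60% of its control area while a lost well drops
    below threshold. Returns (areas DataFrame, truth dict with the per-strain
    active and retained substrate sets).
    """
    rng = np.random.default_rng(seed)
    substrates = [f"source_{i:03d}" for i in range(n_substrates)]
    rows, truth = [], {}
    roles = [(s, retention_tolerant) for s in strains_tolerant] + \
            [(s, retention_sensitive) for s in strains_sensitive]
    for strain, retention in roles:
        active = rng.random(n_substrates) < p_active
        retained = active & (rng.random(n_substrates) < retention)
        truth[strain] = {
            "active": {substrates[i] for i in np.flatnonzero(active)},
            "retained": {substrates[i] for i in np.flatnonzero(retained)},
        }
        for i, sub in enumerate(substrates):
            if active[i]:
                ctrl = rng.uniform(25_000, 60_000)
                salt = ctrl * rng.uniform(0.6, 1.0) if retained[i] \
                    else ctrl * rng.uniform(0.02, 0.15)
            else:
                ctrl = rng.uniform(1_000, 9_000)
                salt = rng.uniform(1_000, 9_000)
            rows.append({"strain": strain, "substrate": sub,
                         "condition": "0", "area": ctrl})
            rows.append({"strain": strain, "substrate": sub,
                         "condition": "300", "area": salt})
    return pd.DataFrame(rows), truth
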