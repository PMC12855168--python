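"""Exact placement of significant k-mers on genomes and their mapping to
genes, promoter windows, pangenome clusters, COG classes and replicons.

A k-mer placed without mismatches on either strand is classified against the
CDS annotation: any overlap with a CDS gives relative position 0 (a gene
hit); a k-mer lying wholly on the 5' side of a CDS start, within 600 nt, is
a regulatory hit with a negative offset; anything farther is intergenic. A
k-mer sitting between two divergent promoters may legitimately receive one
record per eligible CDS. Because k-mers are canonical (strandless), only the
CDS strand decides which direction is upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmers import canonical, canonical_codes, encode_kmer, \
    encode_windows, reverse_complement

PROMOTER_WINDOW = 600  # nt upstream of the CDS start, inclusive at -600


@dataclass
class CdsRecord:
    scaffold_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # '+' or '-'
    locus_id: str
    product: str = ""
    cog_id: str | None = None
    cog_class: str | None = None

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad CDS interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class KmerPlacement:
    kmer: str  # canonical form
    scaffold_id: str
    start: int  # 1-based position of the leftmost matched base
    strand: str  # orientation that matched: '+' canonical, '-' its revcomp

    @property
    def end(self) -> int:
        return self.start + len(self.kmer) - 1


def locate_kmers(kmers, scaffolds) -> list:
    """All exact occurrences of each k-mer or its reverse complement.

    ``scaffolds`` is an iterable of (scaffold_id, sequence). Matches on
    either strand are reported (strand records which orientation matched);
    multiple hits per k-mer are allowed. No mismatches, no gaps.
    """
    placements = []
    scaffolds = list(scaffolds)
    for kmer in kmers:
        kc = canonical(kmer)
        rc = reverse_complement(kc)
        for scaffold_id, seq in scaffolds:
            for query, strand in ((kc, "+"), (rc, "-")):
                if strand == "-" and rc == kc:
                    continue  # palindromic k-mer: one orientation suffices
                pos = seq.find(query)
                while pos != -1:
                    placements.append(KmerPlacement(kc, scaffold_id,
                                                    pos + 1, strand))
                    pos = seq.find(query, pos + 1)
    return placements


def locate_kmers_indexed(kmers, scaffolds) -> list:
    """Same placements as :func:`locate_kmers`, via a sorted window index.

    Scales to thousands of query k-mers per genome: each scaffold's windows
    are encoded once and queries resolved by binary search.
    """
    queries = []
    for kmer in kmers:
        kc = canonical(kmer)
        rc = reverse_complement(kc)
        queries.append((kc, encode_kmer(kc), "+"))
        if rc != kc:
            queries.append((kc, encode_kmer(rc), "-"))
    placements = []
    for scaffold_id, seq in scaffolds:
        ks = {len(q[0]) for q in queries}
        for k in ks:
            positions, fwd = encode_windows(seq, k)
            order = np.argsort(fwd, kind="stable")
            sorted_codes = fwd[order]
            for kc, qcode, strand in queries:
                if len(kc) != k:
                    continue
                lo = np.searchsorted(sorted_codes, qcode, "left")
                hi = np.searchsorted(sorted_codes, qcode, "right")
                for idx in sorted(order[lo:hi]):
                    placements.append(KmerPlacement(kc, scaffold_id,
                                                    int(positions[idx]) + 1,
                                                    strand))
    return placements


def relative_position(placement: KmerPlacement, cds_records,
                      window: int = PROMOTER_WINDOW) -> list:
    """Relative positions of a placement against every eligible CDS.

    Rules: (R1) any base overlap with a CDS -> relative position 0 for that
    CDS; (R2) a k-mer wholly upstream of a CDS start on its 5' side gets a
    negative offset, the distance from the k-mer base nearest the start to
    the start; (R3) one record per eligible CDS (divergent promoters can
    claim the same k-mer twice); (R4) beyond ``window`` nt upstream and
    non-overlapping, the CDS is not eligible.

    Returns a list of (relative_position, locus_id); empty when the k-mer is
    intergenic with respect to every CDS on the scaffold.
    """
    out = []
    a, b = placement.start, placement.end
    for cds in cds_records:
        if cds.scaffold_id != placement.scaffold_id:
            continue
        if a <= cds.end and b >= cds.start:  # R1: >=1 shared base
            out.append((0, cds.locus_id))
            continue
        if cds.strand == "+":
            dist = cds.start - b  # k-mer wholly left of the start
        else:
            dist = a - cds.end    # k-mer wholly right of the start
        if 0 < dist <= window:  # R2/R4: window inclusive at -window
            out.append((-dist, cds.locus_id))
    return out


def classify_hits(placements, cds_records,
                  window: int = PROMOTER_WINDOW) -> pd.DataFrame:
    """Hit table: one row per (placement, eligible CDS), or a single
    intergenic row when no CDS is eligible.

    Columns: kmer, scaffold, start, strand, relative_position, hit_class,
    locus, product, cog_class.
    """
    by_locus = {c.locus_id: c for c in cds_records}
    rows = []
    for p in placements:
        rels = relative_position(p, cds_records, window=window)
        if not rels:
            rows.append({"kmer": p.kmer, "scaffold": p.scaffold_id,
                         "start": p.start, "strand": p.strand,
                         "relative_position": pd.NA,
                         "hit_class": "intergenic", "locus": pd.NA,
                         "product": pd.NA, "cog_class": pd.NA})
            continue
        for rel, locus in rels:
            cds = by_locus[locus]
            rows.append({"kmer": p.kmer, "scaffold": p.scaffold_id,
                         "start": p.start, "strand": p.strand,
                         "relative_position": rel,
                         "hit_class": "gene" if rel == 0 else "regulatory",
                         "locus": locus, "product": cds.product,
                         "cog_class": cds.cog_class})
    cols = ["kmer", "scaffold", "start", "strand", "relative_position",
            "hit_class", "locus", "product", "cog_class"]
    return pd.DataFrame(rows, columns=cols)


def hit_summary(hits: pd.DataFrame) -> dict:
    """Distinct-CDS and distinct-regulatory-region counts from a hit table."""
    gene = hits[hits["hit_class"] == "gene"]
    reg = hits[hits["hit_class"] == "regulatory"]
    return {
        "n_gene_hits": int(len(gene)),
        "n_regulatory_hits": int(len(reg)),
        "n_intergenic": int((hits["hit_class"] == "intergenic").sum()),
        "n_distinct_cds": int(gene["locus"].nunique()),
        "n_distinct_regulatory_regions": int(reg["locus"].nunique()),
    }


def match_to_pangenome(gene_loci, presence_absence: pd.DataFrame):
    """Map hit loci onto pangenome gene clusters.

    ``presence_absence`` has clusters as the index and strains as columns;
    cells hold whitespace/semicolon-separated locus ids (Roary's
    gene_presence_absence layout after dropping its metadata columns, see
    :func:`halogwas.io.read_roary_matrix`). Returns (matches, unmatched):
    ``matches`` maps locus_id -> {"cluster", "n_strains", "strain_unique"}.
    """
    locus_to_cluster = {}
    cluster_strains = {}
    for cluster, row in presence_absence.iterrows():
        strains = set()
        for strain, cell in row.items():
            if pd.isna(cell) or cell == "":
                continue
            strains.add(strain)
            for locus in str(cell).replace(";", " ").replace("\t", " ").split():
                locus_to_cluster[locus] = cluster
        cluster_strains[cluster] = strains
    matches, unmatched = {}, []
    for locus in gene_loci:
        if locus in locus_to_cluster:
            cluster = locus_to_cluster[locus]
            strains = cluster_strains[cluster]
            matches[locus] = {"cluster": cluster,
                              "n_strains": len(strains),
                              "strain_unique": len(strains) == 1}
        else:
            unmatched.append(locus)
    return matches, unmatched


def cog_tally(hits: pd.DataFrame, strain_of=None) -> pd.DataFrame:
    """Frequency table of COG classes over gene hits (rows: classes,
    columns: strains; 'unclassified' rows for hits without a COG label).

    ``strain_of`` maps a hit row to a strain id (callable on the row); when
    omitted all hits are tallied under a single 'panel' column. Multi-letter
    COG classes contribute one count per letter.
    """
    gene = hits[hits["hit_class"] == "gene"]
    counts = {}
    for _, row in gene.iterrows():
        strain = strain_of(row) if strain_of else "panel"
        cls = row.get("cog_class")
        letters = list(cls) if (cls is not None and not pd.isna(cls)
                                and str(cls) != "") else ["unclassified"]
        for letter in letters:
            counts.setdefault(letter, {}).setdefault(strain, 0)
            counts[letter][strain] += 1
    table = pd.DataFrame(counts).T.fillna(0).astype(int)
    return table.sort_index()


@dataclass
class RepliconAssignment:
    scaffold_id: str
    replicon: str  # chromosome / pSymA / pSymB / ... / unknown
    containment: float


def assign_replicons(scaffolds, references, k: int = 13,
                     min_containment: float = 0.5,
                     margin: float = 0.1) -> list:
    """Assign scaffolds to reference replicons by k-mer containment.

    ``references`` maps a replicon label (e.g. chromosome, pSymA, pSymB) to
    its sequence. Containment is the fraction of the scaffold's canonical
    k-mers found in the reference. The best replicon wins when it reaches
    ``min_containment`` and leads the runner-up by at least ``margin``;
    otherwise the scaffold is 'unknown'.
    """
    ref_sets = {label: set(canonical_codes([seq], k).tolist())
                for label, seq in references.items()}
    out = []
    for scaffold_id, seq in scaffolds:
        codes = canonical_codes([seq], k)
        if codes.size == 0:
            out.append(RepliconAssignment(scaffold_id, "unknown", 0.0))
            continue
        fracs = {}
        codeset = set(codes.tolist())
        for label, refset in ref_sets.items():
            fracs[label] = len(codeset & refset) / len(codeset)
        ranked = sorted(fracs.items(), key=lambda kv: (-kv[1], kv[0]))
        best_label, best = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0.0
        if best >= min_containment and best - runner >= margin:
            out.append(RepliconAssignment(scaffold_id, best_label, best))
        else:
            out.append(RepliconAssignment(scaffold_id, "unknown", best))
    return out


def replicon_summary(assignments, labels=("chromosome", "pSymA", "pSymB",
                                          "unknown")) -> pd.DataFrame:
    """Percentage of scaffolds per replicon; percentages sum to 100."""
    n = len(assignments)
    rows = []
    for label in labels:
        count = sum(1 for a in assignments if a.replicon == label)
        rows.append({"replicon": label, "n_scaffolds": count,
                     "percent": 100.0 * count / n if n else 0.0})
    return pd.DataFrame(rows)
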