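"""Association testing between k-mer presence/absence and a continuous
phenotype.

Each retained k-mer splits the panel into carriers and non-carriers; the two
groups are compared with a weighted Welch two-sample t-test in which every
strain contributes with its clonal-structure (GSC) weight. With all weights
equal to 1 the statistic reduces exactly to the classical Welch test.

Weighted moments use the unbiased frequency-weight-corrected estimator:

    m_g   = sum(w_i x_i) / sum(w_i)
    n_g   = sum(w_i)                       (effective group size)
    s_g^2 = sum(w_i (x_i - m_g)^2) * sum(w_i) / (sum(w_i)^2 - sum(w_i^2))

    t  = (m_1 - m_2) / sqrt(s_1^2/n_1 + s_2^2/n_2)
    df = Welch-Satterthwaite on the two variance components
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import GenomePanel, KmerMatrix, build_matrix, decode_kmer, \
    distance_matrix, filter_matrix
from .structure import StructureWeights, build_guide_tree, gsc_weights


class WelchResult(NamedTuple):
    t_stat: float
    df: float
    p_value: float
    n_with: int
    n_without: int


def _weighted_moments(x: np.ndarray, w: np.ndarray):
    sw = w.sum()
    if sw <= 0:
        raise ValueError("zero total weight in group")
    m = float(np.dot(w, x) / sw)
    sw2 = float(np.dot(w, w))
    denom = sw * sw - sw2
    if denom <= 0:
        raise ValueError("degenerate weights (effective group size <= 1)")
    s2 = float(np.dot(w, (x - m) ** 2) * sw / denom)
    return m, s2, float(sw)


def weighted_welch_test(x_with: np.ndarray, w_with: np.ndarray,
                        x_without: np.ndarray,
                        w_without: np.ndarray) -> WelchResult:
    """Weighted Welch two-sample t-test (two-sided).

    Raises ValueError when a group has fewer than two members or no weight.
    """
    if len(x_with) < 2 or len(x_without) < 2:
        raise ValueError("each group needs at least 2 strains")
    m1, s21, n1 = _weighted_moments(np.asarray(x_with, float),
                                    np.asarray(w_with, float))
    m2, s22, n2 = _weighted_moments(np.asarray(x_without, float),
                                    np.asarray(w_without, float))
    v1, v2 = s21 / n1, s22 / n2
    se2 = v1 + v2
    if se2 == 0.0:
        t = 0.0
        df = n1 + n2 - 2
        p = 1.0
    else:
        t = (m1 - m2) / np.sqrt(se2)
        df = se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)),
                       len(x_with), len(x_without))


@dataclass
class GwasConfig:
    k: int = 13
    min_present: int = 2
    min_absent: int = 2
    alpha: float = 0.05
    correct_structure: bool = True
    keep_all: bool = False  # keep k-mers with p > alpha in the output table


@dataclass
class GwasResult:
    """Association table plus the intermediates needed to reproduce it."""

    associations: pd.DataFrame  # kmer, n_with, n_without, t, df, p, q
    weights: StructureWeights | None
    matrix: KmerMatrix  # after filtering
    n_kmers_total: int
    n_kmers_tested: int
    n_skipped: int

    def top(self, top_p: float | None = None,
            top_n: int | None = None) -> pd.DataFrame:
        """Extreme-p subset, by p-value ceiling and/or rank cutoff."""
        out = self.associations
        if top_p is not None:
            out = out[out["p"] <= top_p]
        if top_n is not None:
            out = out.head(top_n)
        return out


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (reporting metadata only)."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def associate_matrix(matrix: KmerMatrix, phenotype: dict,
                weights: StructureWeights | None,
                alpha: float = 0.05, keep_all: bool = False):
    """Run the weighted Welch test for every k-mer of a (filtered) matrix.

    k-mers sharing an identical presence pattern are tested once and share
    the resulting statistic, which leaves the output independent of how the
    matrix is batched. Returns (DataFrame, n_tested, n_skipped).
    """
    strains = [s for s in matrix.strains if s in phenotype]
    if len(strains) < 4:
        raise ValueError("phenotype must cover at least 4 panel strains")
    cols = [matrix.strains.index(s) for s in strains]
    pres = matrix.presence[:, cols]
    x = np.array([phenotype[s] for s in strains], float)
    if weights is None:
        w = np.ones(len(strains))
    else:
        w = weights.aligned(strains)

    if pres.shape[0] == 0:
        empty = pd.DataFrame(columns=["kmer", "n_with", "n_without", "t",
                                      "df", "p", "q"])
        return empty, 0, 0

    packed = np.packbits(pres, axis=1)
    patterns, inverse = np.unique(packed, axis=0, return_inverse=True)
    inverse = np.asarray(inverse).ravel()
    n_pat = patterns.shape[0]
    # recover one representative row per pattern
    rep_rows = np.full(n_pat, -1, dtype=np.int64)
    rep_rows[inverse[::-1]] = np.arange(pres.shape[0] - 1, -1, -1)

    stats_per_pattern = np.full((n_pat, 5), np.nan)
    skipped_patterns = np.zeros(n_pat, dtype=bool)
    for pi in range(n_pat):
        mask = pres[rep_rows[pi]]
        try:
            r = weighted_welch_test(x[mask], w[mask], x[~mask], w[~mask])
        except ValueError:
            skipped_patterns[pi] = True
            continue
        stats_per_pattern[pi] = (r.t_stat, r.df, r.p_value, r.n_with,
                                 r.n_without)

    ok = ~skipped_patterns[inverse]
    n_skipped = int((~ok).sum())
    st = stats_per_pattern[inverse[ok]]
    kmer_strings = [decode_kmer(int(c), matrix.k) for c in matrix.codes[ok]]
    df = pd.DataFrame({
        "kmer": kmer_strings,
        "n_with": st[:, 3].astype(int),
        "n_without": st[:, 4].astype(int),
        "t": st[:, 0],
        "df": st[:, 1],
        "p": st[:, 2],
    })
    df["q"] = _bh_qvalues(df["p"].to_numpy()) if len(df) else []
    n_tested = len(df)
    if not keep_all:
        df = df[df["p"] <= alpha]
    df = df.sort_values(["p", "kmer"], kind="stable").reset_index(drop=True)
    return df, n_tested, n_skipped


def run_gwas(panel: GenomePanel, phenotype: dict,
             config: GwasConfig | None = None,
             log=None) -> GwasResult:
    """Full chain: count -> filter -> structure weights -> weighted Welch.

    ``phenotype`` maps strain_id -> value in [0, 1] (normalized mean
    metabolic activity). Strains missing a phenotype are dropped from the
    tests but still contribute to the guide tree.
    """
    cfg = config or GwasConfig()
    say = log or (lambda msg: None)
    matrix = build_matrix(panel, k=cfg.k)
    say(f"counted {matrix.n_kmers} canonical {cfg.k}-mers "
        f"across {len(matrix.strains)} strains")
    filtered = filter_matrix(matrix, cfg.min_present, cfg.min_absent)
    say(f"filter (min_present={cfg.min_present}, min_absent={cfg.min_absent})"
        f" retained {filtered.n_kmers} k-mers")
    weights = None
    if cfg.correct_structure:
        dm = distance_matrix(matrix)
        tree = build_guide_tree(dm)
        weights = gsc_weights(tree)
        say("computed GSC clonal-structure weights from UPGMA guide tree")
    assoc, n_tested, n_skipped = associate_matrix(
        filtered, phenotype, weights, alpha=cfg.alpha, keep_all=cfg.keep_all)
    say(f"tested {n_tested} k-mers ({n_skipped} skipped); "
        f"{int((assoc['p'] <= cfg.alpha).sum())} at p <= {cfg.alpha}")
    return GwasResult(associations=assoc, weights=weights, matrix=filtered,
                      n_kmers_total=matrix.n_kmers, n_kmers_tested=n_tested,
                      n_skipped=n_skipped)
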