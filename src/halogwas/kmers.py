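"""Canonical k-mer counting and presence/absence matrices across strain panels.

k-mers are collapsed across strands: each window is represented by the
lexicographic minimum of itself and its reverse complement, which makes the
matrix insensitive to the arbitrary orientation of draft-assembly scaffolds.
Internally k-mers are packed into 2-bit-per-base int64 codes so that whole
scaffolds can be processed with vectorised numpy; the public API speaks
strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> 2-bit code; anything else (N, gaps) -> 255 and the window is skipped
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def encode_canonical(seq: str, k: int) -> np.ndarray:
    """Canonical int64 codes for every valid k-window of ``seq``.

    Windows containing a non-ACGT symbol are dropped. The code of a k-mer
    b_0..b_{k-1} is sum(code(b_i) * 4**(k-1-i)); the canonical code is the
    minimum of the forward code and the reverse-complement code. Returns the
    codes in window order (one entry per valid window, duplicates kept).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must fit in an int64 code (k <= 31)")
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    win = win[valid].astype(np.int64)
    pow_fwd = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ pow_fwd
    # revcomp: complement (3 - c) read right-to-left == weights ascending
    pow_rev = 4 ** np.arange(k, dtype=np.int64)
    rev = (3 - win) @ pow_rev
    return np.minimum(fwd, rev)


def encode_windows(seq: str, k: int):
    """(positions, forward_codes) for every valid k-window of ``seq``.

    Positions are 0-based window starts; windows containing non-ACGT
    symbols are dropped. Forward codes are NOT canonicalized.
    """
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    positions = np.flatnonzero(valid)
    win = win[valid].astype(np.int64)
    pow_fwd = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return positions, win @ pow_fwd


def encode_kmer(kmer: str) -> int:
    """Forward int64 code of one k-mer string (ACGT only)."""
    codes = _BASE_CODE[np.frombuffer(kmer.encode("ascii"), dtype=np.uint8)]
    if (codes > 3).any():
        raise ValueError(f"non-ACGT symbol in k-mer {kmer!r}")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def count_kmers(scaffolds, k: int = 13) -> set:
    """Set of canonical k-mers over all scaffolds (both strands collapsed).

    ``scaffolds`` is an iterable of nucleotide strings, or of
    (scaffold_id, sequence) pairs.
    """
    codes = canonical_codes(scaffolds, k)
    return {decode_kmer(int(c), k) for c in codes}


def canonical_codes(scaffolds, k: int = 13) -> np.ndarray:
    """Sorted unique canonical codes over all scaffolds of one strain."""
    seqs = []
    for item in scaffolds:
        seq = item[1] if isinstance(item, tuple) else item
        seqs.append(encode_canonical(seq, k))
    if not seqs:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(seqs))


@dataclass
class GenomePanel:
    """A panel of strain genomes: strain_id -> list of (scaffold_id, sequence)."""

    entries: list  # list of (strain_id, [(scaffold_id, seq), ...])

    def __post_init__(self):
        ids = [sid for sid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate strain_id in panel")
        for sid, scafs in self.entries:
            for scid, seq in scafs:
                if not seq:
                    raise ValueError(f"empty scaffold {scid} in strain {sid}")

    @property
    def strain_ids(self) -> list:
        return [sid for sid, _ in self.entries]

    def scaffolds(self, strain_id: str) -> list:
        for sid, scafs in self.entries:
            if sid == strain_id:
                return scafs
        raise KeyError(strain_id)


@dataclass
class KmerMatrix:
    """Presence/absence of canonical k-mers across a strain panel.

    ``codes`` are sorted unique canonical int64 codes; ``presence`` is a
    boolean (n_kmers, n_strains) array aligned with ``strains``.
    """

    k: int
    strains: list
    codes: np.ndarray
    presence: np.ndarray

    @property
    def n_kmers(self) -> int:
        return len(self.codes)

    def kmer_strings(self) -> list:
        return [decode_kmer(int(c), self.k) for c in self.codes]

    def strain_kmer_codes(self, strain_id: str) -> np.ndarray:
        j = self.strains.index(strain_id)
        return self.codes[self.presence[:, j]]


def build_matrix(panel: GenomePanel, k: int = 13) -> KmerMatrix:
    """Presence bit set iff the k-mer occurs at least once in the strain."""
    if not panel.entries:
        raise ValueError("empty panel")
    per_strain = [canonical_codes(scafs, k) for _, scafs in panel.entries]
    universe = np.unique(np.concatenate([c for c in per_strain if c.size] or
                                        [np.empty(0, dtype=np.int64)]))
    presence = np.zeros((universe.size, len(per_strain)), dtype=bool)
    for j, codes in enumerate(per_strain):
        if codes.size:
            idx = np.searchsorted(universe, codes)
            presence[idx, j] = True
    return KmerMatrix(k=k, strains=panel.strain_ids, codes=universe,
                      presence=presence)


def filter_matrix(m: KmerMatrix, min_present: int = 2,
                  min_absent: int = 2) -> KmerMatrix:
    """Drop k-mers present in fewer than ``min_present`` strains or absent
    from fewer than ``min_absent`` strains (the '-min 2 -max 2' rule)."""
    if min_present < 0 or min_absent < 0:
        raise ValueError("thresholds must be >= 0")
    n = len(m.strains)
    npresent = m.presence.sum(axis=1)
    keep = (npresent >= min_present) & ((n - npresent) >= min_absent)
    return KmerMatrix(k=m.k, strains=list(m.strains), codes=m.codes[keep],
                      presence=m.presence[keep])


def kmer_distance(m: KmerMatrix, strain_a: str, strain_b: str) -> float:
    """Mash-style distance from the Jaccard index of two strains' k-mer sets.

    d = -(1/k) * ln(2J / (1 + J)), capped at 1; d = 1 when J = 0.
    """
    ja = m.presence[:, m.strains.index(strain_a)]
    jb = m.presence[:, m.strains.index(strain_b)]
    na, nb = int(ja.sum()), int(jb.sum())
    if na == 0 or nb == 0:
        raise ValueError("strain with empty k-mer set")
    inter = int((ja & jb).sum())
    union = na + nb - inter
    jac = inter / union
    if jac == 0.0:
        return 1.0
    if jac == 1.0:
        return 0.0
    d = -(1.0 / m.k) * np.log(2 * jac / (1 + jac))
    return float(min(d, 1.0))


def distance_matrix(m: KmerMatrix):
    """Symmetric pairwise Mash-style distance matrix as a pandas DataFrame."""
    import pandas as pd

    n = len(m.strains)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_distance(m, m.strains[i], m.strains[j])
    return pd.DataFrame(d, index=m.strains, columns=m.strains)
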