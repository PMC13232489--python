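"""Genome-wide NGG site index and mismatch-tolerant off-target counting.

Every 20-mer adjacent to an NGG PAM on either strand is encoded as a 2-bit
packed integer; a query is compared against all sites at once with XOR and a
per-base popcount, so counting sites within Hamming distance <= m is a few
vectorised passes over the index. This replaces an external off-target
screen at desk scale; distances are ungapped (no bulges). The same module
provides exact-occurrence counting for primer specificity: a primer is
considered specific when its full-length sequence occurs exactly once in the
genome across both strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeAssembly, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_ODD_MASK = np.uint64(0x5555555555555555)


def _encode_bases(seq: str) -> np.ndarray:
    """Per-base 2-bit codes; 255 marks N/invalid."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pack_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit packed k-mer codes and a validity mask (no N inside)."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    packed = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    safe = np.where(codes == 255, 0, codes).astype(np.uint64)
    for j in range(k):
        packed = (packed << two) | safe[j : j + m]
    bad = (codes == 255).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    return packed, valid


def encode_protospacer(seq: str) -> np.uint64:
    codes = _encode_bases(seq)
    if (codes == 255).any():
        raise ValueError(f"protospacer contains non-ACGT characters: {seq!r}")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return np.uint64(value)


@dataclass
class PamSiteIndex:
    """All NGG-adjacent 20-mers of a genome, both strands.

    Parallel arrays: ``codes`` (2-bit packed protospacers in their own sense),
    ``chrom_idx``, ``strand`` (+1 plus, -1 minus), ``start`` (0-based
    plus-strand coordinate of the protospacer's leftmost base).
    """

    chromosome_names: list[str]
    codes: np.ndarray
    chrom_idx: np.ndarray
    strand: np.ndarray
    start: np.ndarray
    protospacer_length: int = 20

    def __len__(self) -> int:
        return len(self.codes)

    def iter_sites(self):
        """Yield (protospacer, chromosome, strand, start) — decodes the index;
        used to validate against a naive scan."""
        k = self.protospacer_length
        for code, ci, st, pos in zip(self.codes, self.chrom_idx, self.strand, self.start):
            value = int(code)
            proto = "".join(
                "ACGT"[(value >> (2 * (k - 1 - j))) & 3] for j in range(k)
            )
            yield proto, self.chromosome_names[int(ci)], "+" if st > 0 else "-", int(pos)


def build_index(genome: GenomeAssembly, protospacer_length: int = 20) -> PamSiteIndex:
    """Index every NGG-adjacent protospacer on both strands; sites containing
    N are excluded."""
    k = protospacer_length
    names = list(genome.chromosomes)
    all_codes, all_chrom, all_strand, all_start = [], [], [], []
    for ci, name in enumerate(names):
        seq = genome.chromosomes[name]
        codes = _encode_bases(seq)
        n = len(seq)
        if n < k + 3:
            continue
        packed, valid = _pack_kmers(codes, k)
        is_g = codes == 2
        is_c = codes == 1
        # plus strand: 20-mer at i with GG at i+k+1, i+k+2 (PAM N at i+k)
        m = n - (k + 3) + 1
        plus = valid[:m] & is_g[k + 1 : k + 1 + m] & is_g[k + 2 : k + 2 + m]
        plus &= codes[k : k + m] != 255  # PAM N base must be a real base
        pos_plus = np.nonzero(plus)[0]
        all_codes.append(packed[pos_plus])
        all_chrom.append(np.full(len(pos_plus), ci, dtype=np.uint16))
        all_strand.append(np.full(len(pos_plus), 1, dtype=np.int8))
        all_start.append(pos_plus.astype(np.int64))
        # minus strand: plus-strand CC at j, j+1, PAM N at j+2,
        # protospacer occupies [j+3, j+3+k); own-sense code is the
        # reverse complement of that slice
        rc_packed, rc_valid = _pack_kmers(_encode_bases(revcomp(seq)), k)
        minus = is_c[:m] & is_c[1 : 1 + m]
        minus &= codes[2 : 2 + m] != 255
        # revcomp(seq[a:a+k]) starts at n-a-k in the reverse-complemented string
        pos_minus = np.nonzero(minus)[0]
        rc_starts = n - (pos_minus + 3) - k
        keep = rc_valid[rc_starts]
        pos_minus = pos_minus[keep]
        rc_starts = rc_starts[keep]
        all_codes.append(rc_packed[rc_starts])
        all_chrom.append(np.full(len(pos_minus), ci, dtype=np.uint16))
        all_strand.append(np.full(len(pos_minus), -1, dtype=np.int8))
        all_start.append((pos_minus + 3).astype(np.int64))
    if all_codes:
        codes = np.concatenate(all_codes)
        chrom_idx = np.concatenate(all_chrom)
        strand = np.concatenate(all_strand)
        start = np.concatenate(all_start)
    else:
        codes = np.empty(0, dtype=np.uint64)
        chrom_idx = np.empty(0, dtype=np.uint16)
        strand = np.empty(0, dtype=np.int8)
        start = np.empty(0, dtype=np.int64)
    return PamSiteIndex(names, codes, chrom_idx, strand, start, k)


def _mismatch_counts(index: PamSiteIndex, query_code: np.uint64) -> np.ndarray:
    x = index.codes ^ query_code
    y = (x | (x >> np.uint64(1))) & _ODD_MASK
    return np.bitwise_count(y)


def count_offtargets(
    protospacer: str,
    index: PamSiteIndex,
    max_mismatches: int,
    on_target_location: tuple[str, str, int] | None = None,
) -> int:
    """Number of indexed NGG sites within Hamming distance <= max_mismatches
    of the protospacer, excluding the on-target site itself.

    ``on_target_location`` is (chromosome, strand, protospacer start).
    """
    if len(protospacer) != index.protospacer_length:
        raise ValueError(
            f"protospacer length {len(protospacer)} != {index.protospacer_length}"
        )
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if len(index) == 0:
        return 0
    mm = _mismatch_counts(index, encode_protospacer(protospacer))
    hits = mm <= max_mismatches
    count = int(hits.sum())
    if on_target_location is not None:
        chrom, strand, pos = on_target_location
        try:
            ci = index.chromosome_names.index(chrom)
        except ValueError:
            return count
        st = 1 if strand == "+" else -1
        self_mask = hits & (index.chrom_idx == ci) & (index.strand == st) & (
            index.start == pos
        )
        count -= int(self_mask.sum())
    return count


def exact_occurrences(oligo: str, genome: GenomeAssembly) -> int:
    """Exact full-length matches of an oligo on both strands of the genome
    (overlapping occurrences counted; a palindrome at one locus counts twice)."""
    if len(oligo) < 10:
        raise ValueError("oligo must be at least 10 nt")
    total = 0
    targets = (oligo, revcomp(oligo))
    for seq in genome.chromosomes.values():
        for t in targets:
            i = seq.find(t)
            while i != -1:
                total += 1
                i = seq.find(t, i + 1)
    return total
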