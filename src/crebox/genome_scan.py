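"""Both-strand genome scanning with a motif weight matrix.

Every window of motif width on either strand whose sum-of-log-odds score
reaches the cutoff is reported exactly once, with 0-based half-open
coordinates internally and 1-based inclusive coordinates in written outputs.
Lower-strand hits carry the window in motif orientation (reverse complement
of the genomic top strand).  Windows containing N are skipped.

Each hit also records the genomic coordinate of motif position 8, the
conserved central G of the cre box, which downstream modules use as the
anchor for distance measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .motif_model import MotifMatrix

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
#: Central-G motif index (0-based) for the 14-nt cre box; position 8 in 1-based.
CENTRAL_G_INDEX = 7

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("N")] = 4
_ENCODE[ord("n")] = 4


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over ACGTN (case preserved)."""
    bad = set(seq) - set("ACGTNacgtn")
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """A scored, stranded motif occurrence.

    ``start`` is the 0-based genomic coordinate of the hit's first base on
    the top strand; ``site`` is the window read in motif orientation;
    ``g8_position`` is the 0-based genomic coordinate of motif position 8.
    """

    contig: str
    start: int
    strand: str  # '+' (upper) or '-' (lower)
    site: str
    score: float
    g8_position: int

    @property
    def end(self) -> int:
        return self.start + len(self.site)

    @property
    def strand_name(self) -> str:
        return "upper" if self.strand == "+" else "lower"


def _encode(seq: str) -> np.ndarray:
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 4).any() and set(seq.upper()) - set("ACGTN"):
        bad = sorted(set(seq.upper()) - set("ACGTN"))
        raise ValueError(f"genome sequence contains characters {bad}")
    return codes


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score all top-strand windows; NaN where a window contains N."""
    w = log_odds.shape[1]
    L = codes.size
    n_win = L - w + 1
    if n_win <= 0:
        return np.empty(0)
    # pad with a NaN row so code 4 (N) poisons any window containing it
    lo = np.vstack([log_odds, np.full((1, w), np.nan)])
    scores = np.zeros(n_win)
    for j in range(w):
        scores += lo[codes[j : j + n_win], j]
    return scores


def scan_genome(
    matrix: MotifMatrix,
    genome: Mapping[str, str] | Iterable[tuple[str, str]],
    cutoff: float,
    circular: bool = False,
) -> list[MotifHit]:
    """Report every window on either strand scoring at least ``cutoff``.

    ``genome`` maps contig name to sequence (ACGTN).  Hits are sorted by
    contig, then start, then strand ('+' before '-').  Overlapping hits are
    all reported; a palindromic site that clears the cutoff in both
    orientations yields one hit per strand at the same interval.  With
    ``circular`` each contig additionally yields windows wrapping across the
    origin, reported with start near the contig end.
    """
    if matrix.log_odds is None:
        raise ValueError("matrix has no log_odds; call build_weight_matrix first")
    items = genome.items() if isinstance(genome, Mapping) else genome
    w = matrix.width
    # lower-strand hits at top-strand interval [i, i+w) score the reverse
    # complement of that window: fold the strand flip into the matrix
    lo_fwd = matrix.log_odds
    lo_rev = lo_fwd[::-1, ::-1]  # complement rows (T,G,C,A order) + reversed columns

    hits: list[MotifHit] = []
    for contig, seq in items:
        L = len(seq)
        scan_seq = seq + seq[: w - 1] if circular and L >= w else seq
        codes = _encode(scan_seq)
        for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
            scores = _window_scores(codes, lo)
            with np.errstate(invalid="ignore"):
                keep = np.nonzero(scores >= cutoff)[0]
            for i in keep:
                window = scan_seq[i : i + w].upper()
                site = window if strand == "+" else reverse_complement(window)
                g8 = i + CENTRAL_G_INDEX if strand == "+" else i + (w - 1 - CENTRAL_G_INDEX)
                if circular:
                    g8 %= L
                hits.append(
                    MotifHit(contig, int(i), strand, site, float(scores[i]), int(g8))
                )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_bed(hits: Iterable[MotifHit], path: str | Path, max_score: float | None = None) -> None:
    """BED6 output (0-based half-open; name = site in motif orientation).

    BED scores must be integers in 0..1000: when ``max_score`` is given,
    scores are scaled linearly from [0, max_score]; otherwise the raw score
    is rounded and clamped.
    """
    with open(path, "w") as fh:
        for h in hits:
            if max_score:
                s = 1000.0 * h.score / max_score
            else:
                s = h.score
            bed_score = int(min(1000, max(0, round(s))))
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\t{h.site}\t{bed_score}\t{h.strand}\n"
            )


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Full-precision hit table; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tsite\tscore\tg8_position\n")
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start + 1}\t{h.end}\t{h.strand_name}\t"
                f"{h.site}\t{h.score:.2f}\t{h.g8_position + 1}\n"
            )
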