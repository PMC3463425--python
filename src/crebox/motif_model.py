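"""Position frequency / weight matrices for fixed-width DNA motifs.

The cre box is a degenerate 14-nt operator; its sequence model here is the
classical independent-column one: a position frequency matrix (PFM) of base
counts built from an alignment of known sites, smoothed with a pseudocount
into per-column probabilities, and log-odds transformed against a background
base composition.  A candidate window is scored by summing the per-position
log-odds of its bases (base-2, so a perfectly conserved position over uniform
background contributes 2 bits).

Columns are indexed 0..w-1 internally; user-facing strings (consensus,
reports) follow the 1..w convention of the motif literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DNA_ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}

#: Uniform mononucleotide background, the default for log-odds.
UNIFORM_BACKGROUND = np.full(4, 0.25)

#: IUPAC code for each unordered pair of bases (used by consensus calling).
IUPAC_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


def _validate_sequence(seq: str, label: str) -> str:
    """Upper-case *seq* and reject anything outside strict ACGT."""
    up = seq.upper()
    for pos, ch in enumerate(up, start=1):
        if ch not in BASE_INDEX:
            raise ValueError(
                f"sequence {label!r} has non-ACGT character {ch!r} at position {pos}"
            )
    return up


@dataclass(frozen=True)
class MotifAlignment:
    """A gap-free alignment of equal-width DNA sequences over {A,C,G,T}.

    Lower-case input is accepted and upper-cased; RNA (U) and ambiguity
    codes are rejected with the offending sequence and position named.
    """

    sequences: tuple[str, ...]
    ids: tuple[str, ...]

    def __init__(self, sequences: Iterable[str], ids: Iterable[str] | None = None):
        seqs = list(sequences)
        if not seqs:
            raise ValueError("alignment must contain at least one sequence")
        labels = list(ids) if ids is not None else [f"seq{i + 1}" for i in range(len(seqs))]
        if len(labels) != len(seqs):
            raise ValueError("ids and sequences differ in length")
        seqs = [_validate_sequence(s, lab) for s, lab in zip(seqs, labels)]
        widths = {len(s) for s in seqs}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment: widths {sorted(widths)}")
        object.__setattr__(self, "sequences", tuple(seqs))
        object.__setattr__(self, "ids", tuple(labels))

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MotifAlignment":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([str(r.seq) for r in records], [r.id for r in records])

    @classmethod
    def from_text(cls, path: str | Path) -> "MotifAlignment":
        """One sequence per line; blank lines and ``#`` comments ignored."""
        seqs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                seqs.append(line)
        return cls(seqs)


@dataclass
class MotifMatrix:
    """Count / probability / log-odds matrices of a fixed-width motif.

    ``counts`` is 4 x w (rows in A, C, G, T order); each column sums to the
    training-set size.  ``probabilities`` are pseudocount-smoothed column
    distributions; ``log_odds`` (populated by :func:`build_weight_matrix`) is
    log2(probability / background).
    """

    counts: np.ndarray
    n_sequences: int
    pseudocount: float = 0.5
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    log_odds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must be 4 x w")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts.sum(axis=0), self.n_sequences):
            raise ValueError("each counts column must sum to the training-set size")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        return (self.counts + self.pseudocount) / (
            self.n_sequences + 4.0 * self.pseudocount
        )

    @property
    def frequencies(self) -> np.ndarray:
        """Raw (un-smoothed) column frequencies counts / N."""
        return self.counts / float(self.n_sequences)


def build_pfm(alignment: MotifAlignment, pseudocount: float = 0.5) -> MotifMatrix:
    """Tally a position frequency matrix from an aligned site set."""
    counts = np.zeros((4, alignment.width))
    for seq in alignment.sequences:
        for j, ch in enumerate(seq):
            counts[BASE_INDEX[ch], j] += 1
    return MotifMatrix(counts, n_sequences=len(alignment), pseudocount=pseudocount)


def build_weight_matrix(
    pfm: MotifMatrix,
    background: Sequence[float] | np.ndarray | None = None,
    pseudocount: float | None = None,
) -> MotifMatrix:
    """Attach base-2 log-odds to a PFM.

    log_odds[b, i] = log2( (counts[b, i] + k) / (N + 4k) / background[b] )
    with pseudocount k.  With k = 0, absent bases get -inf, which is kept
    as-is: such windows can never pass a finite score cutoff.
    """
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    if bg.shape != (4,):
        raise ValueError("background must supply 4 base frequencies")
    if (bg <= 0).any():
        raise ValueError("background frequencies must be positive")
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background frequencies must sum to 1")
    k = pfm.pseudocount if pseudocount is None else pseudocount
    if k < 0:
        raise ValueError("pseudocount must be non-negative")
    probs = (pfm.counts + k) / (pfm.n_sequences + 4.0 * k)
    with np.errstate(divide="ignore"):
        lo = np.log2(probs / bg[:, None])
    return MotifMatrix(
        pfm.counts,
        n_sequences=pfm.n_sequences,
        pseudocount=k,
        background=bg,
        log_odds=lo,
    )


def consensus_call(
    pfm: MotifMatrix, theta_single: float = 0.70, theta_pair: float = 0.75
) -> str:
    """Call a degenerate IUPAC consensus from raw column frequencies.

    Per column: the top base if its frequency is at least ``theta_single``;
    otherwise the two-base IUPAC code of the top two bases if their combined
    frequency reaches ``theta_pair``; otherwise N.  Ties are broken
    alphabetically.  The thresholds are a heuristic calibrated to the cre
    literature's single- vs two-base calls; they are not a published rule.
    """
    for name, theta in (("theta_single", theta_single), ("theta_pair", theta_pair)):
        if not 0.5 < theta <= 1.0:
            raise ValueError(f"{name} must lie in (0.5, 1], got {theta}")
    freqs = pfm.frequencies
    out = []
    for j in range(pfm.width):
        col = freqs[:, j]
        # sort by descending frequency, alphabetical base on ties
        order = sorted(range(4), key=lambda b: (-col[b], DNA_ALPHABET[b]))
        top, second = order[0], order[1]
        if col[top] >= theta_single:
            out.append(DNA_ALPHABET[top])
        elif col[top] + col[second] >= theta_pair:
            out.append(IUPAC_PAIR[frozenset((DNA_ALPHABET[top], DNA_ALPHABET[second]))])
        else:
            out.append("N")
    return "".join(out)


def score_window(matrix: MotifMatrix, window: str) -> float | None:
    """Sum-of-log-odds score of one window; None if the window is unscorable.

    Returns None (a sentinel distinguishable from any real score) when the
    window contains a base outside ACGT, e.g. an N from a genome assembly.
    """
    if matrix.log_odds is None:
        raise ValueError("matrix has no log_odds; call build_weight_matrix first")
    window = window.upper()
    if len(window) != matrix.width:
        raise ValueError(
            f"window width {len(window)} != matrix width {matrix.width}"
        )
    total = 0.0
    for j, ch in enumerate(window):
        idx = BASE_INDEX.get(ch)
        if idx is None:
            return None
        total += matrix.log_odds[idx, j]
    return total


def best_window(matrix: MotifMatrix) -> str:
    """The maximal-scoring window: per-column argmax of the log-odds."""
    if matrix.log_odds is None:
        raise ValueError("matrix has no log_odds; call build_weight_matrix first")
    return "".join(
        DNA_ALPHABET[int(np.argmax(matrix.log_odds[:, j]))] for j in range(matrix.width)
    )


def score_quantile(
    matrix: MotifMatrix,
    q: float,
    model: np.ndarray | None = None,
    grid: float = 1e-3,
) -> float:
    """Exact q-quantile of the window score under a column-independent model.

    The score of a window drawn column-independently from ``model`` (4 x w
    column distributions; default: the matrix's own smoothed probabilities,
    i.e. the motif model itself) is a sum of independent discrete variables;
    its distribution is computed exactly by convolution over columns on a
    score grid of resolution ``grid``.  The returned threshold t satisfies
    P(score < t) <= q, so scanning with cutoff t keeps a false-negative rate
    of at most q for true sites drawn from ``model``.

    Requires finite log-odds (a positive pseudocount) wherever the model
    puts mass.
    """
    if matrix.log_odds is None:
        raise ValueError("matrix has no log_odds; call build_weight_matrix first")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    p = matrix.probabilities if model is None else np.asarray(model, float)
    if p.shape != matrix.log_odds.shape:
        raise ValueError("model must be 4 x w matching the matrix")
    if not np.isfinite(matrix.log_odds[p > 0]).all():
        raise ValueError("infinite log-odds carry model probability; use a pseudocount")
    scaled = np.rint(matrix.log_odds / grid)
    scaled[p == 0] = 0.0  # value irrelevant at zero mass
    scaled = scaled.astype(np.int64)
    dist = {0: 1.0}
    for j in range(matrix.width):
        nxt: dict[int, float] = {}
        for b in range(4):
            pb = p[b, j]
            if pb == 0.0:
                continue
            sb = scaled[b, j]
            for s, mass in dist.items():
                key = s + sb
                nxt[key] = nxt.get(key, 0.0) + mass * pb
        dist = nxt
    scores = np.array(sorted(dist))
    cdf = np.cumsum([dist[s] for s in scores])
    idx = int(np.searchsorted(cdf, q, side="left"))
    return float(scores[min(idx, len(scores) - 1)] * grid)


# ---------------------------------------------------------------------------
# matrix I/O: JASPAR-style counts, TSV log-odds
# ---------------------------------------------------------------------------

def write_jaspar_pfm(matrix: MotifMatrix, path: str | Path, name: str = "motif") -> None:
    """Write counts in JASPAR text form, e.g. ``A  [ 2  0 ]``."""
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for b in DNA_ALPHABET:
            row = " ".join(
                f"{matrix.counts[BASE_INDEX[b], j]:g}" for j in range(matrix.width)
            )
            fh.write(f"{b}  [ {row} ]\n")


def read_jaspar_pfm(path: str | Path, pseudocount: float = 0.5) -> MotifMatrix:
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([list(motif.counts[b]) for b in DNA_ALPHABET])
    n = int(round(counts[:, 0].sum()))
    return MotifMatrix(counts, n_sequences=n, pseudocount=pseudocount)


def write_log_odds_tsv(matrix: MotifMatrix, path: str | Path) -> None:
    """Tab-separated 4 x w log-odds table at full precision (repr round-trip)."""
    if matrix.log_odds is None:
        raise ValueError("matrix has no log_odds to write")
    with open(path, "w") as fh:
        fh.write("base\t" + "\t".join(str(j + 1) for j in range(matrix.width)) + "\n")
        for b in DNA_ALPHABET:
            vals = "\t".join(repr(float(v)) for v in matrix.log_odds[BASE_INDEX[b]])
            fh.write(f"{b}\t{vals}\n")


def read_log_odds_tsv(path: str | Path) -> np.ndarray:
    rows: dict[str, list[float]] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        parts = line.split("\t")
        rows[parts[0]] = [float(x) for x in parts[1:]]
    return np.array([rows[b] for b in DNA_ALPHABET])
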