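"""Palindromicity statistics for fixed-width operator sequences.

The cre box is pseudo-palindromic: a dimeric regulator prefers operators
whose two half-sites read as reverse complements of each other.  For an
even-width w-mer the palindrome score counts the symmetric position pairs
(i, w+1-i), 1-based, whose bases are Watson-Crick complementary; a perfect
palindrome of width 14 scores 7 (and equals its own reverse complement).

Group profiles give, per position, the percentage of sequences whose pair
containing that position is complementary (the row is symmetric about the
center by construction) and the group's mean score.  Rounding is half-up,
with percentages passed through a one-decimal intermediate (the display
convention of common spreadsheet software, and the one that matches curated
reference tables in this field): e.g. 34/38 -> 89.47 -> 89.5 -> 90.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 always away from zero upward)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(x).quantize(q, rounding=ROUND_HALF_UP))


def _percent(count: int, n: int) -> int:
    # half-up through a one-decimal intermediate; see module docstring
    return int(round_half_up(round_half_up(100.0 * count / n, 1), 0))


@dataclass(frozen=True)
class PalindromeResult:
    """Score and symmetric pair mask of one sequence.

    ``pair_mask[i]`` is True when position i+1 belongs to a complementary
    pair; the mask is symmetric and the score is half its True count.
    """

    sequence: str
    score: int
    pair_mask: tuple[bool, ...]


@dataclass(frozen=True)
class GroupProfile:
    """Per-position palindrome percentages and mean score of a sequence set."""

    n: int
    percent: tuple[int, ...]
    mean_score: float


def palindrome_score(seq: str) -> PalindromeResult:
    """Count complementary symmetric pairs of an even-width sequence.

    A pair containing an ambiguous base (e.g. N) counts as non-palindromic
    rather than raising, so genome-scanned sites can still be profiled.
    """
    seq = seq.upper()
    w = len(seq)
    if w == 0 or w % 2:
        raise ValueError(f"palindrome score needs a non-empty even width, got {w}")
    half = w // 2
    mask = [False] * w
    score = 0
    for i in range(half):
        j = w - 1 - i
        if COMPLEMENT.get(seq[i]) == seq[j]:
            mask[i] = mask[j] = True
            score += 1
    return PalindromeResult(seq, score, tuple(mask))


def group_profile(seqs: Sequence[str]) -> GroupProfile:
    """Per-position palindrome percentages and half-up mean over a set."""
    if not seqs:
        raise ValueError("group profile needs at least one sequence")
    widths = {len(s) for s in seqs}
    if len(widths) != 1:
        raise ValueError(f"ragged sequence widths: {sorted(widths)}")
    results = [palindrome_score(s) for s in seqs]
    n = len(results)
    w = widths.pop()
    percent = tuple(_percent(sum(r.pair_mask[i] for r in results), n) for i in range(w))
    mean = round_half_up(sum(r.score for r in results) / n, 1)
    return GroupProfile(n, percent, mean)


def pair_mask_render(result: PalindromeResult, marker: tuple[str, str] = ("[", "]")) -> str:
    """Wrap paired positions in markers, e.g. TGAAA[T]GA[A]TCGTT-style output.

    Stripping the markers recovers the plain sequence exactly.
    """
    open_, close = marker
    return "".join(
        f"{open_}{ch}{close}" if flag else ch
        for ch, flag in zip(result.sequence, result.pair_mask)
    )


def load_sequences(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from FASTA or two-column TSV."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        from Bio import SeqIO

        return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    pairs = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("id\t"):
            continue
        name, seq = line.split("\t")[:2]
        pairs.append((name, seq))
    return pairs


def write_profile_tsv(
    named_seqs: Sequence[tuple[str, str]], path: str | Path
) -> GroupProfile:
    """Per-sequence scores plus the bottom percentage row and mean."""
    profile = group_profile([s for _, s in named_seqs])
    with open(path, "w") as fh:
        fh.write("id\tsequence\tscore\n")
        for name, seq in named_seqs:
            fh.write(f"{name}\t{seq}\t{palindrome_score(seq).score}\n")
        fh.write("palindrome_%\t" + " ".join(map(str, profile.percent)) + "\t\n")
        fh.write(f"mean_score\t{profile.mean_score}\t\n")
    return profile
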