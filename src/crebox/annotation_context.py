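"""Attach motif hits to operon first genes and compute anchored distances.

Only sites near a promoter can plausibly regulate: predicted hits are kept
when the conserved central G of the site falls within a window (default
-500..+100 nt, closed on both ends) around the first base of the start codon
of an operon's first gene, measured in the gene's reading direction.
Literature-curated sites bypass the window.  Distances to the transcription
start site (TSS), when a TSS is known, use the same central-G anchor:
negative = upstream of the anchor, positive = downstream, 0 = at the anchor.

Coordinates are 0-based internally; TSV/GFF3 input and all written output
are 1-based inclusive.  Sign conventions follow the regulated gene's reading
direction regardless of which strand carries the cre site itself.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_scan import MotifHit

DEFAULT_WINDOW = (-500, 100)

_REQUIRED_COLUMNS = ("gene_id", "operon_id", "strand", "start_codon")


@dataclass(frozen=True)
class GeneContext:
    """An operon first gene: the positional anchor for cre sites.

    ``start_codon`` is the 0-based genomic coordinate of the first base of
    the start codon in reading direction; ``tss`` likewise, or None when not
    determined.
    """

    gene_id: str
    operon_id: str
    strand: str  # '+' or '-'
    start_codon: int
    tss: int | None = None
    contig: str = "genome"


@dataclass(frozen=True)
class CreSite:
    """A cre occurrence attached to a gene, with anchored distances.

    ``dist_start_codon`` / ``dist_tss`` are signed offsets of the site's
    central G from the respective anchor in the gene's reading direction
    (None when the coordinate or the TSS is unknown).  ``source`` is
    'predicted' for scan hits and 'literature' for curated sites.
    """

    gene: GeneContext
    sequence: str
    strand: str
    g8_position: int | None
    dist_start_codon: int | None
    dist_tss: int | None
    source: str = "predicted"
    hit: MotifHit | None = None

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id


def signed_offset(position: int, anchor: int, gene_strand: str) -> int:
    """Offset of *position* from *anchor* in the gene's reading direction."""
    if gene_strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {gene_strand!r}")
    return position - anchor if gene_strand == "+" else anchor - position


def _parse_tss(value) -> int | None:
    if value is None or (isinstance(value, str) and value.strip() in ("", "ND", "NA")):
        return None
    if pd.isna(value):
        return None
    return int(value) - 1  # 1-based input -> 0-based


def load_annotation(path: str | Path, contig: str = "genome") -> list[GeneContext]:
    """Read gene contexts from TSV or GFF3 and keep one per operon first gene.

    TSV columns: gene_id, operon_id, strand, start_codon (1-based), optional
    tss (1-based or ND) and contig.  GFF3: ``gene`` features; the operon id
    is taken from an ``operon`` attribute when present, else each gene is a
    singleton operon.  For a gene on '-' with span [s, e] the start codon's
    first base in reading direction is e.  When an operon lists several
    genes, the most promoter-proximal one (smallest start codon in reading
    direction) is kept.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        contexts = _load_gff3(path)
    else:
        contexts = _load_tsv(path, contig)
    ids = [c.gene_id for c in contexts]
    dupes = {g for g in ids if ids.count(g) > 1}
    if dupes:
        raise ValueError(f"duplicate gene_id in annotation: {sorted(dupes)}")
    return _first_genes(contexts)


def _load_tsv(path: Path, default_contig: str) -> list[GeneContext]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "operon_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation is missing mandatory columns: {missing}")
    contexts = []
    for row in df.itertuples(index=False):
        operon = getattr(row, "operon_id")
        if operon is None or (isinstance(operon, float) and pd.isna(operon)):
            operon = row.gene_id  # unassigned genes become singleton operons
        contexts.append(
            GeneContext(
                gene_id=row.gene_id,
                operon_id=str(operon),
                strand=row.strand,
                start_codon=int(row.start_codon) - 1,
                tss=_parse_tss(getattr(row, "tss", None)),
                contig=str(getattr(row, "contig", default_contig)),
            )
        )
    return contexts


def _load_gff3(path: Path) -> list[GeneContext]:
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(path), tmp.name, force=True, keep_order=True, merge_strategy="error"
        )
        contexts = []
        for feat in db.features_of_type("gene"):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            operon = feat.attributes.get("operon", [gene_id])[0]
            start_codon = feat.start - 1 if feat.strand == "+" else feat.end - 1
            tss_attr = feat.attributes.get("tss", [None])[0]
            contexts.append(
                GeneContext(
                    gene_id=gene_id,
                    operon_id=operon,
                    strand=feat.strand,
                    start_codon=start_codon,
                    tss=_parse_tss(tss_attr),
                    contig=feat.seqid,
                )
            )
    return contexts


def _first_genes(contexts: Sequence[GeneContext]) -> list[GeneContext]:
    by_operon: dict[str, GeneContext] = {}
    for ctx in contexts:
        cur = by_operon.get(ctx.operon_id)
        if cur is None:
            by_operon[ctx.operon_id] = ctx
            continue
        # promoter-proximal = smallest coordinate in reading direction
        if ctx.strand == "+":
            if ctx.start_codon < cur.start_codon:
                by_operon[ctx.operon_id] = ctx
        else:
            if ctx.start_codon > cur.start_codon:
                by_operon[ctx.operon_id] = ctx
    return sorted(by_operon.values(), key=lambda c: (c.contig, c.start_codon))


def _make_site(
    gene: GeneContext,
    sequence: str,
    strand: str,
    g8: int | None,
    source: str,
    hit: MotifHit | None = None,
) -> CreSite:
    dist_sc = None if g8 is None else signed_offset(g8, gene.start_codon, gene.strand)
    dist_tss = (
        None
        if g8 is None or gene.tss is None
        else signed_offset(g8, gene.tss, gene.strand)
    )
    return CreSite(gene, sequence, strand, g8, dist_sc, dist_tss, source, hit)


def assign_hits(
    hits: Iterable[MotifHit],
    contexts: Iterable[GeneContext],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[CreSite]:
    """Attach each hit to every first gene whose window contains its central G.

    One hit may attach to several genes (divergent promoters) and a gene may
    collect several hits; pairs outside the closed window are dropped.
    """
    lo, hi = window
    sites = []
    for ctx in contexts:
        for hit in hits:
            if hit.contig != ctx.contig:
                continue
            d = signed_offset(hit.g8_position, ctx.start_codon, ctx.strand)
            if lo <= d <= hi:
                sites.append(
                    _make_site(ctx, hit.site, hit.strand, hit.g8_position, "predicted", hit)
                )
    return sites


def add_known_sites(
    table: pd.DataFrame | str | Path,
    contexts: Iterable[GeneContext],
    predicted: Sequence[CreSite] = (),
) -> list[CreSite]:
    """Merge literature-curated sites with predicted ones.

    ``table`` (TSV or DataFrame) columns: gene_id, sequence, strand, and an
    optional 1-based g8_position.  Curated sites bypass the positional
    window; a curated site duplicating a predicted one (same gene, same
    central-G coordinate) replaces it, keeping source='literature'.  Sites
    without coordinates get absent distances but remain classifiable.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    by_gene = {c.gene_id: c for c in contexts}
    merged: list[CreSite] = list(predicted)
    for row in table.itertuples(index=False):
        gene = by_gene.get(row.gene_id)
        if gene is None:
            raise KeyError(f"literature site names unknown gene_id {row.gene_id!r}")
        g8_raw = getattr(row, "g8_position", None)
        g8 = None if g8_raw is None or pd.isna(g8_raw) else int(g8_raw) - 1
        site = _make_site(gene, str(row.sequence).upper(), row.strand, g8, "literature")
        merged = [
            s
            for s in merged
            if not (s.gene_id == site.gene_id and s.g8_position is not None and s.g8_position == g8)
        ]
        merged.append(site)
    return merged


def cre_tss_distance(site: CreSite) -> int | None:
    """Signed central-G-to-TSS offset; None (never 0) when the TSS is unknown."""
    if site.gene.tss is None or site.g8_position is None:
        return None
    return signed_offset(site.g8_position, site.gene.tss, site.gene.strand)


def write_sites_tsv(sites: Iterable[CreSite], path: str | Path) -> None:
    """CreSite table; absent distances written as ND, coordinates 1-based."""

    def nd(v) -> str:
        return "ND" if v is None else str(v)

    with open(path, "w") as fh:
        fh.write(
            "gene_id\toperon_id\tsequence\tcre_strand\tg8_position\t"
            "dist_start_codon\tdist_tss\tsource\n"
        )
        for s in sites:
            g8 = "ND" if s.g8_position is None else str(s.g8_position + 1)
            fh.write(
                f"{s.gene_id}\t{s.gene.operon_id}\t{s.sequence}\t{s.strand}\t{g8}\t"
                f"{nd(s.dist_start_codon)}\t{nd(s.dist_tss)}\t{s.source}\n"
            )
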