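"""Synthetic genomes with planted cre sites and matching expression tables.

The generator emulates the study design the classifier assumes: a bacterial
genome (i.i.d. background at a chosen GC content) hosting operons whose
first genes carry planted cre sites of graded affinity.  Strong-class site
sequences are drawn from the high-affinity cre frequency matrix, weak-class
from the low-affinity one, activating sites from the high-affinity matrix
(the observed activating sites match that consensus better), and decoys are
random 14-mers kept only if they score below the scan cutoff.  Sites sit at
TSS distances drawn from a mixture of a near-TSS cluster and a uniform
spread, mirroring the observed positional preference of strong sites.

Expression fold changes are built per gene from class-specific noise-free
effects (uniform on the fold-change scale within per-class, per-dose
ranges), perturbed with Gaussian noise on the log2 scale, and converted to
the signed-ratio convention (|fc| >= 1; negative = repressed).  Strong sites
repress at all three doses, weak sites only at medium/high, activating
sites activate at all three; genes without a functional site have zero true
effect.  Significance flags are |fc| >= 1.8 on the emitted (noisy) value,
optionally corrupted at a false-flag rate.

Everything is driven by a single seed; two runs from equal specs are
byte-identical.  A truth table records planted coordinates, classes and
noise-free effects for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .affinity_pipeline import ExpressionRecord
from .annotation_context import GeneContext, signed_offset
from .genome_scan import CENTRAL_G_INDEX, MotifHit, reverse_complement
from .motif_model import (
    DNA_ALPHABET,
    MotifMatrix,
    build_pfm,
    build_weight_matrix,
    score_quantile,
    score_window,
)

STRONG, WEAK, ACTIVATING, DECOY, NONE = "strong", "weak", "activating", "decoy", "none"
_REGULATED = (STRONG, WEAK, ACTIVATING)

#: noise-free |fold change| ranges per class at (low, med, high) doses.
#: Spans of the observed regulon data, inset from the 1.8 decision threshold
#: by roughly the noise scale so planted labels stay identifiable under the
#: default noise model (a noise-free effect sitting exactly on the threshold
#: would make the planted label a coin flip).
DEFAULT_EFFECT_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    STRONG: ((2.0, 7.4), (2.5, 21.9), (2.5, 35.8)),
    WEAK: ((1.0, 1.5), (2.0, 6.6), (2.0, 12.2)),
    ACTIVATING: ((2.0, 6.2), (2.0, 6.2), (2.0, 6.2)),
}


@dataclass
class SyntheticSpec:
    """All knobs of the generator; one seed drives every random draw."""

    seed: int = 0
    genome_length: int = 200_000
    gc_content: float = 0.435  # B. subtilis-like
    n_operons: int = 70
    n_strong: int = 20
    n_weak: int = 20
    n_activating: int = 3
    n_decoy: int = 20
    leader_range: tuple[int, int] = (20, 80)  # TSS to start codon, nt
    near_tss_frac: float = 0.7
    near_tss_sd: float = 15.0
    uniform_range: tuple[int, int] = (-100, 120)
    effect_ranges: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_EFFECT_RANGES.items()})
    noise_sd: float = 0.25  # Gaussian sd on log2 fold changes
    false_flag_rate: float = 0.0
    site_width: int = 14

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.n_sites > self.n_operons:
            raise ValueError(
                f"{self.n_sites} planted sites need at least that many operons "
                f"(n_operons={self.n_operons})"
            )
        slot = self.genome_length // self.n_operons
        need = 2 * (max(abs(self.uniform_range[0]), abs(self.uniform_range[1]))
                    + self.leader_range[1] + self.site_width + 10)
        if slot < need:
            raise ValueError(
                f"genome too short: {self.n_operons} operons leave {slot} nt "
                f"per operon but placement needs ~{need}"
            )

    @property
    def n_sites(self) -> int:
        return self.n_strong + self.n_weak + self.n_activating + self.n_decoy

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("leader_range", "uniform_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "effect_ranges" in raw:
            raw["effect_ranges"] = {
                k: tuple(tuple(r) for r in v) for k, v in raw["effect_ranges"].items()
            }
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class SyntheticDataset:
    """Genome, annotation and planted-site truth emitted by one spec."""

    spec: SyntheticSpec
    genome: dict[str, str]
    contexts: list[GeneContext]
    truth_sites: pd.DataFrame


def default_matrices(pseudocount: float = 0.5) -> dict[str, MotifMatrix]:
    """Weight matrices trained on the bundled regulon table.

    Keys: 'strong', 'weak' (per affinity group) and 'combined' (all
    repressing sites) — the combined matrix is the genome-scan motif.
    """
    from . import datasets

    out = {}
    for key, aln in (
        ("strong", datasets.reference_alignment("high")),
        ("weak", datasets.reference_alignment("low")),
        ("combined", datasets.repressing_alignment()),
    ):
        out[key] = build_weight_matrix(build_pfm(aln, pseudocount))
    return out


def calibrated_cutoff(
    scan_matrix: MotifMatrix,
    site_models: Sequence[MotifMatrix],
    fnr: float = 0.01,
) -> float:
    """Scan cutoff keeping the false-negative rate <= ``fnr`` per site class.

    For each class model, the exact quantile of the scan-matrix score of
    sites drawn from that model is computed by column convolution; the
    minimum over classes is returned, so no class loses more than ``fnr`` of
    its true sites at the cutoff.
    """
    return min(
        score_quantile(scan_matrix, fnr, model=m.probabilities) for m in site_models
    )


def _sample_site(rng: np.random.Generator, probs: np.ndarray) -> str:
    return "".join(
        DNA_ALPHABET[rng.choice(4, p=probs[:, j] / probs[:, j].sum())]
        for j in range(probs.shape[1])
    )


def _sample_decoy(
    rng: np.random.Generator, width: int, scan_matrix: MotifMatrix, cutoff: float
) -> str:
    for _ in range(1000):
        seq = "".join(DNA_ALPHABET[b] for b in rng.integers(0, 4, width))
        s = score_window(scan_matrix, seq)
        if s is not None and s < cutoff:
            return seq
    raise RuntimeError("could not sample a decoy below the scan cutoff")


def generate_genome(
    spec: SyntheticSpec,
    matrices: Mapping[str, MotifMatrix] | None = None,
    scan_cutoff: float | None = None,
) -> SyntheticDataset:
    """Build the genome, its operon annotation and the planted-site truth.

    ``matrices`` defaults to :func:`default_matrices`; ``scan_cutoff`` (used
    only to reject decoys that would look like real sites) defaults to the
    1%-FNR calibrated cutoff of the combined matrix.
    """
    rng = np.random.default_rng(spec.seed)
    mats = default_matrices() if matrices is None else dict(matrices)
    if scan_cutoff is None:
        scan_cutoff = calibrated_cutoff(
            mats["combined"], [mats["strong"], mats["weak"]]
        )
    w = spec.site_width
    gc = spec.gc_content
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=spec.genome_length, p=base_probs)
    genome_arr = np.array(list(DNA_ALPHABET), dtype="U1")[codes]

    classes = ([STRONG] * spec.n_strong + [WEAK] * spec.n_weak
               + [ACTIVATING] * spec.n_activating + [DECOY] * spec.n_decoy
               + [NONE] * (spec.n_operons - spec.n_sites))
    classes = [classes[i] for i in rng.permutation(len(classes))]

    seq_model = {
        STRONG: mats["strong"].probabilities,
        WEAK: mats["weak"].probabilities,
        ACTIVATING: mats["strong"].probabilities,
    }
    slot = spec.genome_length // spec.n_operons
    contexts: list[GeneContext] = []
    site_rows = []
    for k, klass in enumerate(classes):
        lo_bound, hi_bound = k * slot, (k + 1) * slot
        center = lo_bound + slot // 2
        strand = "+" if rng.random() < 0.5 else "-"
        leader = int(rng.integers(spec.leader_range[0], spec.leader_range[1] + 1))
        tss = center
        start_codon = tss + leader if strand == "+" else tss - leader
        gene = f"gene{k:03d}"
        contexts.append(
            GeneContext(gene, f"op{k:03d}", strand, start_codon, tss, contig="synthetic_chr")
        )
        if klass == NONE:
            continue

        for attempt in range(100):
            if rng.random() < spec.near_tss_frac:
                d = int(round(rng.normal(0.0, spec.near_tss_sd)))
            else:
                d = int(rng.integers(spec.uniform_range[0], spec.uniform_range[1] + 1))
            g8 = tss + d if strand == "+" else tss - d
            site_strand = "+" if rng.random() < 0.5 else "-"
            start = g8 - CENTRAL_G_INDEX if site_strand == "+" else g8 - (w - 1 - CENTRAL_G_INDEX)
            if lo_bound + 1 <= start and start + w <= hi_bound - 1:
                break
        else:
            raise RuntimeError(
                f"operon {k}: no site placement satisfied the slot bounds "
                f"[{lo_bound}, {hi_bound}) after 100 draws"
            )

        if klass == DECOY:
            site_seq = _sample_decoy(rng, w, mats["combined"], scan_cutoff)
        else:
            site_seq = _sample_site(rng, seq_model[klass])
        embedded = site_seq if site_strand == "+" else reverse_complement(site_seq)
        genome_arr[start : start + w] = list(embedded)
        site_rows.append(
            dict(
                gene=gene, operon=f"op{k:03d}", klass=klass,
                site_strand=site_strand, start=start, g8_position=g8,
                sequence=site_seq,
                dist_tss=signed_offset(g8, tss, strand),
                dist_start_codon=signed_offset(g8, start_codon, strand),
            )
        )

    genome = {"synthetic_chr": "".join(genome_arr)}
    truth_sites = pd.DataFrame(site_rows)
    return SyntheticDataset(spec, genome, contexts, truth_sites)


def _log2_to_ratio(x: float) -> float:
    return float(2.0**x) if x >= 0 else float(-(2.0 ** (-x)))


def generate_expression(
    dataset: SyntheticDataset, spec: SyntheticSpec | None = None
) -> tuple[list[ExpressionRecord], pd.DataFrame]:
    """Noisy three-dose expression records plus the noise-free truth.

    Returns ``(records, truth)``: one record per gene in the annotation and
    a truth table with the planted class and the noise-free signed-ratio
    fold changes.  Reproducible from the spec's seed independently of
    genome generation.
    """
    spec = dataset.spec if spec is None else spec
    rng = np.random.default_rng([spec.seed, 1])
    klass_by_gene = dict(zip(dataset.truth_sites.get("gene", []),
                             dataset.truth_sites.get("klass", [])))
    records: list[ExpressionRecord] = []
    truth_rows = []
    for ctx in dataset.contexts:
        klass = klass_by_gene.get(ctx.gene_id, NONE)
        true_log2 = np.zeros(3)
        if klass in _REGULATED:
            sign = 1.0 if klass == ACTIVATING else -1.0
            for i, (lo, hi) in enumerate(spec.effect_ranges[klass]):
                mag = rng.uniform(lo, hi)  # uniform on the fold-change scale
                true_log2[i] = sign * np.log2(mag)
        noisy = true_log2 + rng.normal(0.0, spec.noise_sd, size=3)
        fc = [_log2_to_ratio(x) for x in noisy]
        sig = [abs(r) >= 1.8 for r in fc]
        if spec.false_flag_rate > 0:
            flips = rng.random(3) < spec.false_flag_rate
            sig = [s ^ f for s, f in zip(sig, flips)]
        records.append(
            ExpressionRecord(
                gene_id=ctx.gene_id,
                fc_low=fc[0], fc_med=fc[1], fc_high=fc[2],
                sig_low=sig[0], sig_med=sig[1], sig_high=sig[2],
            )
        )
        truth_rows.append(
            dict(
                gene=ctx.gene_id, klass=klass,
                true_fc_low=_log2_to_ratio(true_log2[0]),
                true_fc_med=_log2_to_ratio(true_log2[1]),
                true_fc_high=_log2_to_ratio(true_log2[2]),
            )
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# recovery scoring against the truth table
# ---------------------------------------------------------------------------

def site_recovery(hits: Sequence[MotifHit], truth_sites: pd.DataFrame) -> float:
    """Fraction of planted non-decoy sites found at exact (start, strand)."""
    planted = truth_sites[truth_sites["klass"].isin(_REGULATED)]
    if planted.empty:
        return float("nan")
    found = {(h.start, h.strand) for h in hits}
    ok = sum(
        (int(r.start), r.site_strand) in found for r in planted.itertuples(index=False)
    )
    return ok / len(planted)


def false_positive_hits(hits: Sequence[MotifHit], truth_sites: pd.DataFrame) -> int:
    """Scan hits not matching any planted site interval (background matches)."""
    planted = set()
    if len(truth_sites):
        planted = {(int(r.start), r.site_strand) for r in truth_sites.itertuples(index=False)}
    return sum((h.start, h.strand) not in planted for h in hits)


_CLASS_TO_CALL = {
    STRONG: "high_affinity",
    WEAK: "low_affinity",
    ACTIVATING: "activating",
}


def label_recovery(calls: Mapping[str, str], truth_expression: pd.DataFrame) -> float:
    """Fraction of planted regulated genes whose affinity call matches truth."""
    planted = truth_expression[truth_expression["klass"].isin(_REGULATED)]
    if planted.empty:
        return float("nan")
    ok = sum(
        calls.get(r.gene) == _CLASS_TO_CALL[r.klass]
        for r in planted.itertuples(index=False)
    )
    return ok / len(planted)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: SyntheticDataset,
    records: Sequence[ExpressionRecord],
    truth_expression: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit FASTA, annotation (TSV + GFF3), expression TSV and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.tsv",
        "gff3": outdir / "annotation.gff3",
        "expression": outdir / "expression.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_expression": outdir / "truth_expression.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for name, seq in dataset.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(paths["annotation"], "w") as fh:
        fh.write("gene_id\toperon_id\tstrand\tstart_codon\ttss\tcontig\n")
        for c in dataset.contexts:
            tss = "ND" if c.tss is None else str(c.tss + 1)
            fh.write(
                f"{c.gene_id}\t{c.operon_id}\t{c.strand}\t{c.start_codon + 1}\t{tss}\t{c.contig}\n"
            )
    contig = next(iter(dataset.genome))
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for c in dataset.contexts:
            # the feature spans the coding gene only; the TSS is an attribute
            if c.strand == "+":
                lo, hi = c.start_codon, c.start_codon + 299
            else:
                lo, hi = c.start_codon - 299, c.start_codon
            attrs = f"ID={c.gene_id};operon={c.operon_id}"
            if c.tss is not None:
                attrs += f";tss={c.tss + 1}"
            fh.write(
                f"{contig}\tcrebox\tgene\t{lo + 1}\t{hi + 1}\t.\t{c.strand}\t.\t{attrs}\n"
            )
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\tfc_low\tfc_med\tfc_high\tsig_low\tsig_med\tsig_high\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.fc_low:.6g}\t{r.fc_med:.6g}\t{r.fc_high:.6g}\t"
                f"{int(r.sig_low)}\t{int(r.sig_med)}\t{int(r.sig_high)}\n"
            )
    sites = dataset.truth_sites.copy()
    if len(sites):
        sites["start"] = sites["start"] + 1  # 1-based in files
        sites["g8_position"] = sites["g8_position"] + 1
    sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    truth_expression.to_csv(paths["truth_expression"], sep="\t", index=False, float_format="%.6g")
    return paths
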