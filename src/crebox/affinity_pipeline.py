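"""Three-level affinity classification of cre sites from expression data.

The regulator (CcpA) is induced at three doses; per-gene signed fold changes
(ratio convention: |fc| >= 1, negative = repressed) with upstream-computed
significance flags are the input.  The titration logic: a site whose operon
is already significantly repressed at the LOW dose binds the scarce
regulator first (high affinity); one repressed only at medium/high doses is
outcompeted until regulator is plentiful (low affinity); operons
significantly activated at all three doses form the small activating class.
Genes not significantly regulated at the high dose cannot be placed at all
and stay unclassified.

A condition counts as significant only when BOTH the flag is set and the
fold-change magnitude reaches the threshold (default 1.8): the flags encode
an upstream p-value criterion that magnitude alone does not capture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.8
CONDITIONS = ("low", "med", "high")

HIGH_AFFINITY = "high_affinity"
LOW_AFFINITY = "low_affinity"
ACTIVATING = "activating"
UNCLASSIFIED = "unclassified"
NO_DATA = "no_data"

_GROUP_ORDER = {HIGH_AFFINITY: 0, LOW_AFFINITY: 1, ACTIVATING: 2, UNCLASSIFIED: 3, NO_DATA: 4}


@dataclass(frozen=True)
class ExpressionRecord:
    """Signed fold changes and significance flags at the three doses."""

    gene_id: str
    fc_low: float
    fc_med: float
    fc_high: float
    sig_low: bool
    sig_med: bool
    sig_high: bool
    exclude: bool = False

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            if getattr(self, f"fc_{cond}") == 0:
                raise ValueError(f"{self.gene_id}: fold change at {cond} is zero")

    def fc(self, cond: str) -> float:
        return getattr(self, f"fc_{cond}")

    def sig(self, cond: str) -> bool:
        return getattr(self, f"sig_{cond}")


@dataclass(frozen=True)
class AffinityCall:
    """Classification outcome with the evidence it used."""

    gene_id: str
    call: str
    direction: str  # 'repressed' | 'activated' | 'none'
    evidence: tuple[tuple[float, bool], ...] = field(default_factory=tuple)


def is_significant(fc: float, sig: bool, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True iff the flag is set AND |fc| reaches the threshold."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    if fc == 0:
        raise ValueError("fold change of 0 is not a valid signed ratio")
    return bool(sig) and abs(fc) >= threshold


def classify_cre(rec: ExpressionRecord, threshold: float = DEFAULT_THRESHOLD) -> AffinityCall:
    """Decision tree over the three (fold change, flag) pairs.

    Regulation at the high dose (either direction) gates entry; then:
    significant repression at low -> high_affinity; significant activation at
    all three -> activating; significant repression at medium or high ->
    low_affinity; anything else unclassified.  Mixed significant directions
    are refused (unclassified) with a warning, never silently.
    """
    evidence = tuple((rec.fc(c), rec.sig(c)) for c in CONDITIONS)
    sig_neg = [is_significant(rec.fc(c), rec.sig(c), threshold) and rec.fc(c) < 0 for c in CONDITIONS]
    sig_pos = [is_significant(rec.fc(c), rec.sig(c), threshold) and rec.fc(c) > 0 for c in CONDITIONS]

    if any(sig_neg) and any(sig_pos):
        logger.warning(
            "%s: conflicting significant directions across doses; unclassified", rec.gene_id
        )
        return AffinityCall(rec.gene_id, UNCLASSIFIED, "none", evidence)
    if not (sig_neg[2] or sig_pos[2]):
        # not regulated at the high dose: outside the analyzable set
        return AffinityCall(rec.gene_id, UNCLASSIFIED, "none", evidence)
    if sig_neg[0]:
        return AffinityCall(rec.gene_id, HIGH_AFFINITY, "repressed", evidence)
    if all(sig_pos):
        return AffinityCall(rec.gene_id, ACTIVATING, "activated", evidence)
    if any(sig_pos):
        logger.warning(
            "%s: significant activation at only some doses; unclassified", rec.gene_id
        )
        return AffinityCall(rec.gene_id, UNCLASSIFIED, "none", evidence)
    if sig_neg[1] or sig_neg[2]:
        return AffinityCall(rec.gene_id, LOW_AFFINITY, "repressed", evidence)
    return AffinityCall(rec.gene_id, UNCLASSIFIED, "none", evidence)


def count_regulated_operons(
    records: Iterable[ExpressionRecord],
    operon_map: Mapping[str, str],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[int, int, int]:
    """Distinct operons significantly repressed at each dose (low, med, high).

    An operon with several cre boxes (several records mapping to it) is
    counted once per dose.
    """
    repressed: list[set[str]] = [set(), set(), set()]
    for rec in records:
        operon = operon_map.get(rec.gene_id, rec.gene_id)
        for i, cond in enumerate(CONDITIONS):
            if is_significant(rec.fc(cond), rec.sig(cond), threshold) and rec.fc(cond) < 0:
                repressed[i].add(operon)
    return tuple(len(s) for s in repressed)  # type: ignore[return-value]


def load_expression(path: str | Path) -> list[ExpressionRecord]:
    """Read the expression TSV (gene_id, fc_*, sig_*, optional exclude_flag)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = ["gene_id"] + [f"fc_{c}" for c in CONDITIONS] + [f"sig_{c}" for c in CONDITIONS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"expression table is missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        rec = ExpressionRecord(
            gene_id=row.gene_id,
            fc_low=float(row.fc_low),
            fc_med=float(row.fc_med),
            fc_high=float(row.fc_high),
            sig_low=bool(row.sig_low),
            sig_med=bool(row.sig_med),
            sig_high=bool(row.sig_high),
            exclude=bool(getattr(row, "exclude_flag", False)),
        )
        for cond in CONDITIONS:
            if rec.sig(cond) and abs(rec.fc(cond)) < DEFAULT_THRESHOLD:
                logger.warning(
                    "%s: flagged significant at %s but |fc|=%.2f < %.1f",
                    rec.gene_id, cond, abs(rec.fc(cond)), DEFAULT_THRESHOLD,
                )
        records.append(rec)
    return records


def tabulate_report(
    sites: Sequence,  # CreSite-like: gene_id, sequence, strand, dist_tss
    records: Mapping[str, ExpressionRecord],
    calls: Mapping[str, AffinityCall],
) -> pd.DataFrame:
    """Per-site report grouped high-affinity / low-affinity / activating.

    Unclassified sites land in a residual section after the three groups;
    sites without an expression record get call 'no_data' and are logged.
    Probe-orientation exclusions (exclude flag on the record) stay in the
    report, marked, for downstream sequence/position analyses to drop.
    Ordering is deterministic: group, then gene_id.
    """
    rows = []
    for site in sites:
        gene = site.gene_id
        rec = records.get(gene)
        call = calls.get(gene)
        if rec is None or call is None:
            logger.warning("site %s has no expression record; reported as no_data", gene)
            rows.append(
                dict(
                    gene_id=gene, cre_strand=site.strand, cre_sequence=site.sequence,
                    fc_low=None, fc_med=None, fc_high=None,
                    dist_tss=site.dist_tss, call=NO_DATA, excluded=False,
                )
            )
            continue
        rows.append(
            dict(
                gene_id=gene, cre_strand=site.strand, cre_sequence=site.sequence,
                fc_low=rec.fc_low, fc_med=rec.fc_med, fc_high=rec.fc_high,
                dist_tss=site.dist_tss, call=call.call, excluded=rec.exclude,
            )
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["_order"] = df["call"].map(_GROUP_ORDER)
    df = df.sort_values(["_order", "gene_id"], kind="stable").drop(columns="_order")
    return df.reset_index(drop=True)


def write_report_tsv(report: pd.DataFrame, path: str | Path) -> None:
    out = report.copy()
    if "dist_tss" in out.columns:
        out["dist_tss"] = out["dist_tss"].map(lambda v: "ND" if v is None or pd.isna(v) else int(v))
    out.to_csv(path, sep="\t", index=False)


def write_counts_tsv(counts: tuple[int, int, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("condition\tregulated_operons\n")
        for cond, n in zip(CONDITIONS, counts):
            fh.write(f"{cond}\t{n}\n")
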