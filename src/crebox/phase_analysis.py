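"""Operator-to-TSS distance and helical-phase summaries.

Regulators bound to the same face of the DNA double helix recur at
multiples of the helical period (~10.5 bp for B-DNA), so the effectiveness
of an operator can depend on its distance to the transcription start site
modulo that period.  This module reduces a classified cre-site table to a
scatter-ready (distance, fold change, group) table and a phase-binned
summary; it is descriptive and fits no periodic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PERIOD = 10.5  # nt per B-DNA helical turn
DEFAULT_BIN_WIDTH = 1.5


def helical_phase(dist: float, period: float = DEFAULT_PERIOD) -> float:
    """Distance modulo the helical period, mapped into [0, period).

    Floored (mathematical) modulo, so negative distances land correctly:
    -27 at period 10.5 gives 4.5.
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    return float(dist % period)


@dataclass(frozen=True)
class PhaseRecord:
    """One classified site on the phase axis."""

    gene_id: str
    dist_tss: int
    fc_high: float
    call: str
    phase: float


def phase_summary(
    report: pd.DataFrame,
    period: float = DEFAULT_PERIOD,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter table and phase-binned summary from a classified site report.

    ``report`` needs columns gene_id, dist_tss, fc_low, fc_med, fc_high,
    call (an affinity-group report works as-is); rows with unknown distance
    are excluded here but untouched elsewhere.  Returns ``(scatter,
    binned)``: the scatter table adds a ``phase`` column; the binned table
    gives, per affinity group and phase bin, the site count and the median
    |fc| at the high dose.  Bin counts conserve the number of sites with a
    known distance.
    """
    known = report[report["dist_tss"].notna()].copy() if len(report) else report.copy()
    if len(known) == 0:
        logger.warning("phase analysis: no site has a known cre-to-TSS distance")
        empty = pd.DataFrame(
            columns=["call", "bin", "phase_lo", "phase_hi", "n", "median_abs_fc_high"]
        )
        return known, empty
    known["dist_tss"] = known["dist_tss"].astype(int)
    known["phase"] = known["dist_tss"].map(lambda d: helical_phase(d, period))

    n_bins = int(np.ceil(period / bin_width))
    known["_bin"] = np.minimum((known["phase"] // bin_width).astype(int), n_bins - 1)
    grouped = (
        known.groupby(["call", "_bin"])
        .agg(n=("gene_id", "size"), median_abs_fc_high=("fc_high", lambda s: float(np.median(np.abs(s)))))
        .reset_index()
        .rename(columns={"_bin": "bin"})
    )
    grouped["phase_lo"] = grouped["bin"] * bin_width
    grouped["phase_hi"] = np.minimum((grouped["bin"] + 1) * bin_width, period)
    binned = grouped[["call", "bin", "phase_lo", "phase_hi", "n", "median_abs_fc_high"]]
    scatter = known.drop(columns="_bin")
    return scatter.reset_index(drop=True), binned.sort_values(["call", "bin"]).reset_index(drop=True)


def write_phase_tsv(
    scatter: pd.DataFrame,
    binned: pd.DataFrame,
    scatter_path: str | Path,
    binned_path: str | Path,
    max_abs_distance: float | None = None,
) -> None:
    """Write both tables; the scatter output optionally caps |distance|.

    The cap only trims the plotted scatter (far-downstream outliers compress
    any figure axis); the full binned table is always written, and callers
    keep the uncapped scatter in memory.
    """
    out = scatter
    if max_abs_distance is not None:
        out = scatter[scatter["dist_tss"].abs() <= max_abs_distance]
    out.to_csv(scatter_path, sep="\t", index=False)
    binned.to_csv(binned_path, sep="\t", index=False)
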