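"""Bundled reference data.

One curated table ships with the package: the *B. subtilis* CcpA-regulon
cre boxes of operon first genes, with the cre 14-mer, the strand carrying
it, signed expression fold changes at three CcpA induction doses with
significance flags, the central-G-to-TSS distance (ND when no TSS is
known), and the published affinity group (high / low / activating).  It is
both a worked example and the training data for the default cre motif
matrices.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .affinity_pipeline import ExpressionRecord
from .motif_model import MotifAlignment

_TABLE = "ccpa_regulon_cre.tsv"


def load_reference_table() -> pd.DataFrame:
    """The curated CcpA-regulon cre table as a DataFrame.

    Columns: gene, operon, strand (upper/lower), cre_sequence, fc_low,
    sig_low, fc_med, sig_med, fc_high, sig_high, dist_tss ('ND' allowed),
    group.
    """
    with resources.files(__package__).joinpath("data", _TABLE).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"gene": str, "operon": str, "dist_tss": str})
    for c in ("sig_low", "sig_med", "sig_high"):
        df[c] = df[c].astype(bool)
    return df


def reference_alignment(group: str) -> MotifAlignment:
    """Aligned cre 14-mers of one affinity group ('high' or 'low')."""
    df = load_reference_table()
    sub = df[df["group"] == group]
    if sub.empty:
        raise ValueError(f"unknown affinity group {group!r}")
    return MotifAlignment(sub["cre_sequence"].tolist(), sub["gene"].tolist())


def repressing_alignment() -> MotifAlignment:
    """All repressing (high + low affinity) cre boxes as one training set.

    Activating sites are excluded: activation may involve extra flanking
    determinants and the class is too small to model.
    """
    df = load_reference_table()
    sub = df[df["group"].isin(["high", "low"])]
    return MotifAlignment(sub["cre_sequence"].tolist(), sub["gene"].tolist())


def reference_expression_records() -> list[ExpressionRecord]:
    """The reference table as ExpressionRecord objects (one per cre box)."""
    df = load_reference_table()
    return [
        ExpressionRecord(
            gene_id=r.gene,
            fc_low=r.fc_low, fc_med=r.fc_med, fc_high=r.fc_high,
            sig_low=r.sig_low, sig_med=r.sig_med, sig_high=r.sig_high,
        )
        for r in df.itertuples(index=False)
    ]


def reference_operon_map() -> dict[str, str]:
    """gene -> operon for the reference table (merges multi-cre operons)."""
    df = load_reference_table()
    return dict(zip(df["gene"], df["operon"]))
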