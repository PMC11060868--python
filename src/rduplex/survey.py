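"""Global surveys of transcripts and RNA-RNA interactions in a dataset.

The counting unit for transcript abundance is the *arm occurrence*: an
intra-RNA chimera contributes 2 to its transcript, an inter-RNA chimera 1 to
each partner.  This makes the per-sample sum of transcript counts equal
exactly twice the read count, and makes the transcript table the margin of
the interaction table.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import DuplexDataSet

__all__ = [
    "top_transcripts",
    "top_interactions",
    "feature_info",
    "get_interactions",
    "get_reverse_interactions",
    "exchange_orientation",
]

log = logging.getLogger(__name__)


def _arm_counts(ds: DuplexDataSet) -> pd.DataFrame:
    rows = []
    for s in ds.sample_names:
        for d in ds.inputFiles[s]:
            rows.append((d.tx_L, s))
            rows.append((d.tx_R, s))
    return pd.DataFrame(rows, columns=["transcript", "sampleName"])


def top_transcripts(ds: DuplexDataSet, n: int = 20) -> pd.DataFrame:
    """Rank transcripts by total duplex-arm occurrences, descending.

    Returns at most ``n`` rows with one count column per sample plus a
    ``total``; ties broken lexicographically by transcript id.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    arms = _arm_counts(ds)
    if arms.empty:
        return pd.DataFrame(columns=["transcript", *ds.sample_names, "total"])
    table = (
        arms.groupby(["transcript", "sampleName"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=ds.sample_names, fill_value=0)
    )
    table["total"] = table.sum(axis=1)
    table = table.sort_values(
        by=["total", "transcript"], ascending=[False, True], kind="stable"
    )
    return table.head(n).reset_index().rename_axis(None, axis=1)


def top_interactions(ds: DuplexDataSet, n: int = 20) -> pd.DataFrame:
    """Rank unordered transcript pairs by total supporting read count.

    Intra-RNA pairs (tx_a == tx_b) are included; (a, b) and (b, a) rows of
    the input merge into one.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rows = []
    for s in ds.sample_names:
        for d in ds.inputFiles[s]:
            a, b = sorted((d.tx_L, d.tx_R))
            rows.append((a, b, s))
    if not rows:
        return pd.DataFrame(columns=["tx_a", "tx_b", *ds.sample_names, "total"])
    df = pd.DataFrame(rows, columns=["tx_a", "tx_b", "sampleName"])
    table = (
        df.groupby(["tx_a", "tx_b", "sampleName"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=ds.sample_names, fill_value=0)
    )
    table["total"] = table.sum(axis=1)
    table = table.sort_values(
        by=["total", "tx_a", "tx_b"], ascending=[False, True, True], kind="stable"
    )
    return table.head(n).reset_index().rename_axis(None, axis=1)


def feature_info(
    ds: DuplexDataSet, delimiter: str = "|", field_index: int = -1
) -> pd.DataFrame:
    """Aggregate arm occurrences by the feature/biotype field of transcript ids.

    The feature class is parsed from each transcript id as the
    ``field_index``-th ``delimiter``-separated field (default: last).  Ids
    without the delimiter are binned as "unclassified".
    """
    arms = _arm_counts(ds)

    def classify(tx: str) -> str:
        if delimiter not in tx:
            log.warning("transcript id %r lacks %r; binned as unclassified", tx, delimiter)
            return "unclassified"
        return tx.split(delimiter)[field_index]

    if arms.empty:
        return pd.DataFrame(columns=["feature", *ds.sample_names, "total"])
    arms["feature"] = arms["transcript"].map(classify)
    table = (
        arms.groupby(["feature", "sampleName"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=ds.sample_names, fill_value=0)
    )
    table["total"] = table.sum(axis=1)
    table = table.sort_values(
        by=["total", "feature"], ascending=[False, True], kind="stable"
    )
    return table.reset_index().rename_axis(None, axis=1)


def get_interactions(ds: DuplexDataSet, partner_ids: list[str]) -> pd.DataFrame:
    """Duplexes linking the RNA of interest to each listed partner.

    One row per duplex with the arm position on the RNA of interest and on
    the partner.  Unknown partners yield no rows (warning logged).
    """
    seen: set[str] = set()
    rows = []
    for s in ds.sample_names:
        for d in ds.inputFiles[s]:
            if d.tx_L == ds.rna_id and d.tx_R in partner_ids and d.tx_R != ds.rna_id:
                seen.add(d.tx_R)
                rows.append(
                    (s, d.read_id, d.tx_R, d.L.start, d.L.end, d.R.start, d.R.end)
                )
            elif d.tx_R == ds.rna_id and d.tx_L in partner_ids and d.tx_L != ds.rna_id:
                seen.add(d.tx_L)
                rows.append(
                    (s, d.read_id, d.tx_L, d.R.start, d.R.end, d.L.start, d.L.end)
                )
    for p in partner_ids:
        if p not in seen:
            log.warning("partner %r has no duplexes with %r", p, ds.rna_id)
    return pd.DataFrame(
        rows,
        columns=[
            "sampleName",
            "read_id",
            "partner",
            "rna_start",
            "rna_end",
            "partner_start",
            "partner_end",
        ],
    )


def exchange_orientation(df: pd.DataFrame) -> pd.DataFrame:
    """Swap the rna_* and partner_* position columns of an interaction table.

    An involution: applying it twice returns the original table.
    """
    swapped = df.rename(
        columns={
            "rna_start": "partner_start",
            "rna_end": "partner_end",
            "partner_start": "rna_start",
            "partner_end": "rna_end",
        }
    )
    return swapped[list(df.columns)]


def get_reverse_interactions(ds: DuplexDataSet, partner_ids: list[str]) -> pd.DataFrame:
    """Same rows as :func:`get_interactions` with the reporting orientation
    exchanged (positions on the partner reported in the rna_* columns)."""
    return exchange_orientation(get_interactions(ds, partner_ids))
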