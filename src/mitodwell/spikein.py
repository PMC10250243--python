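"""Spike-in scaling of CUT&Tag read counts.

Each sample carries a known proportion of Drosophila S2 spike-in cells, so
reads aligning to the fly genome measure per-sample recovery efficiency.  The
raw scaling value of a sample is an arbitrary constant (100 000 for a 10%
spike-in; 200 000 for 20%) divided by its fly read count; scalings are then
normalized so the asynchronous reference sample equals exactly 1, which makes
mitotic and asynchronous signal directly comparable.  The choice of constant
cancels in the normalized scalings.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SpikeInError", "compute_scaling", "normalize_counts", "scatter_pairs"]

SITE_COLUMNS = ["chrom", "start", "end"]  # 0-based half-open BED convention


class SpikeInError(ValueError):
    pass


def compute_scaling(
    table: pd.DataFrame,
    constant: int = 100_000,
    reference: str | None = None,
) -> pd.DataFrame:
    """Add raw and reference-normalized scaling values to a count table.

    ``table`` needs columns ``sample``, ``condition`` and ``fly_reads``; the
    reference is either named explicitly, flagged in an ``is_reference``
    column, or defaults to the first asynchronous sample.  Returns a copy
    with ``constant``, ``raw_scaling = constant / fly_reads`` and ``scaling =
    raw_scaling / raw_scaling(reference)`` (reference scaling is exactly 1).
    """
    required = {"sample", "condition", "fly_reads"}
    if not required <= set(table.columns):
        raise SpikeInError(f"count table needs columns {sorted(required)}")
    out = table.copy()
    bad = out.loc[out["fly_reads"] <= 0, "sample"].tolist()
    if bad:
        raise SpikeInError(f"non-positive fly read counts for samples: {bad}")

    if reference is None:
        if "is_reference" in out.columns and out["is_reference"].any():
            reference = str(out.loc[out["is_reference"], "sample"].iloc[0])
        else:
            asyn = out[out["condition"] == "asynchronous"]
            if asyn.empty:
                raise SpikeInError("no asynchronous reference sample in table")
            reference = str(asyn["sample"].iloc[0])
    if reference not in set(out["sample"]):
        raise SpikeInError(f"reference sample {reference!r} not in table")

    out["constant"] = constant
    out["raw_scaling"] = constant / out["fly_reads"]
    ref_raw = float(out.loc[out["sample"] == reference, "raw_scaling"].iloc[0])
    out["scaling"] = out["raw_scaling"] / ref_raw
    out["is_reference"] = out["sample"] == reference
    return out


def normalize_counts(matrix: pd.DataFrame, scaling_table: pd.DataFrame) -> pd.DataFrame:
    """Multiply each sample column of a site-by-sample count matrix by its
    spike-in scaling value.

    ``matrix`` has the BED-style site columns ``chrom, start, end`` followed
    by one integer-count column per sample.  Scaled counts are kept as real
    numbers (no re-rounding); the reference sample's counts are unchanged.
    """
    sample_cols = [c for c in matrix.columns if c not in SITE_COLUMNS]
    scalings = dict(zip(scaling_table["sample"], scaling_table["scaling"]))
    missing = sorted(set(sample_cols) - set(scalings))
    extra = sorted(set(scalings) - set(sample_cols))
    if missing:
        raise SpikeInError(f"samples missing from scaling table: {missing}")
    if extra:
        logger.info("scaling table has samples absent from the matrix: %s", extra)
    out = matrix.copy()
    for c in sample_cols:
        out[c] = matrix[c].astype(float) * scalings[c]
    return out


def scatter_pairs(
    normalized: pd.DataFrame,
    scaling_table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Paired asynchronous-vs-mitotic normalized counts for scatter plots.

    ``pairs`` lists (asynchronous sample, mitotic sample) tuples; by default
    samples are paired in table order (first asynchronous with first mitotic,
    and so on).  Returns one row per site and pair with columns suitable for
    a log-log scatter.
    """
    cond = dict(zip(scaling_table["sample"], scaling_table["condition"]))
    if pairs is None:
        asyn = [s for s in scaling_table["sample"] if cond[s] == "asynchronous"]
        mito = [s for s in scaling_table["sample"] if cond[s] == "mitotic"]
        pairs = list(zip(asyn, mito))
    rows = []
    for a, m in pairs:
        if a not in normalized.columns or m not in normalized.columns:
            raise SpikeInError(f"pair ({a!r}, {m!r}) not present in the normalized matrix")
        sub = normalized[SITE_COLUMNS].copy()
        sub["asynchronous_sample"] = a
        sub["mitotic_sample"] = m
        sub["asynchronous_count"] = normalized[a].to_numpy()
        sub["mitotic_count"] = normalized[m].to_numpy()
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)
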