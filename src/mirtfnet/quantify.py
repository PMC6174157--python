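"""Count containers and within-sample normalization (RPKM, miRNA TPM, CPM).

The paired design is carried on a :class:`CountMatrix`: an integer
feature x sample table plus per-sample metadata (pair id, tumor/normal
condition, total clean reads, uniquely mapped reads).  Three normalizations
are provided, each with the denominator its convention prescribes:

* RPKM  -- count / (length_kb * uniquely_mapped_reads / 1e6); mRNA-seq.
* TPM   -- count / total_clean_reads * 1e6; the small-RNA "tags per
  million" convention, whose per-sample denominator is the clean-read
  total, not the mapped total, so column sums are <= 1e6.
* CPM   -- count / column_sum * 1e6; column sums are exactly 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

CONDITIONS = ("tumor", "normal")

SAMPLE_COLUMNS = ("pair_id", "condition", "total_clean_reads", "uniquely_mapped_reads")


@dataclass
class CountMatrix:
    """Integer read counts (features x samples) with paired-sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, index = feature ids, columns = sample ids.
    samples
        DataFrame indexed by sample id with columns ``pair_id``,
        ``condition`` (``tumor``/``normal``), ``total_clean_reads`` and
        ``uniquely_mapped_reads``.  Every pair id must map to exactly one
        tumor and one normal sample.
    feature_lengths
        Optional per-feature summed exonic length in nt (required for RPKM).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    feature_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.samples = self.samples.copy()
        if self.counts.empty:
            raise InputError("count matrix is empty")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise InputError("counts must be numeric")
        if (vals < 0).any():
            raise InputError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise InputError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise InputError(f"sample metadata lacks columns: {missing}")
        if list(self.samples.index) != list(self.counts.columns):
            self.samples = self.samples.reindex(self.counts.columns)
            if self.samples.isna().any().any():
                raise InputError("sample metadata does not cover all count columns")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise InputError(f"unknown conditions: {sorted(bad)}")
        for pair_id, grp in self.samples.groupby("pair_id"):
            conds = sorted(grp["condition"])
            if conds != ["normal", "tumor"]:
                raise InputError(
                    f"pair {pair_id!r} must have exactly one tumor and one normal "
                    f"sample, got conditions {conds}"
                )
        colsums = self.counts.sum(axis=0)
        short = [
            s
            for s in self.samples.index
            if self.samples.at[s, "total_clean_reads"] < colsums[s]
        ]
        if short:
            raise InputError(
                f"total_clean_reads below the column count sum for samples: {short}"
            )
        if self.feature_lengths is not None:
            self.feature_lengths = self.feature_lengths.reindex(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def pair_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.samples["pair_id"]:
            seen.setdefault(p, None)
        return list(seen)

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample column count sums."""
        return self.counts.sum(axis=0)

    def pair_samples(self, pair_id: str) -> tuple[str, str]:
        """Return ``(tumor_sample_id, normal_sample_id)`` for a pair."""
        grp = self.samples[self.samples["pair_id"] == pair_id]
        if grp.empty:
            raise InputError(f"unknown pair id {pair_id!r}")
        tumor = grp.index[grp["condition"] == "tumor"]
        normal = grp.index[grp["condition"] == "normal"]
        if len(tumor) != 1 or len(normal) != 1:
            raise InputError(f"pair {pair_id!r} lacks a tumor/normal sample")
        return tumor[0], normal[0]


@dataclass
class NormalizedMatrix:
    """Non-negative normalized expression values with their unit."""

    values: pd.DataFrame
    unit: str
    samples: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.unit not in {"RPKM", "TPM", "CPM"}:
            raise InputError(f"unknown unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise InputError("normalized values must be non-negative")


def compute_rpkm(counts: CountMatrix) -> NormalizedMatrix:
    """Reads per kilobase of exonic length per million uniquely mapped reads."""
    if counts.feature_lengths is None:
        raise InputError("feature lengths are required for RPKM")
    lengths = counts.feature_lengths
    missing = list(lengths.index[lengths.isna() | (lengths <= 0)])
    if missing:
        raise InputError(f"missing or non-positive lengths for features: {missing}")
    mapped = counts.samples["uniquely_mapped_reads"]
    zero = [s for s in mapped.index if mapped[s] <= 0]
    if zero:
        raise InputError(f"zero uniquely mapped reads for samples: {zero}")
    kb = lengths.to_numpy(dtype=float)[:, None] / 1e3
    per_million = mapped.to_numpy(dtype=float)[None, :] / 1e6
    vals = counts.counts.to_numpy(dtype=float) / (kb * per_million)
    df = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    return NormalizedMatrix(df, "RPKM", counts.samples)


def compute_tpm_mirna(counts: CountMatrix) -> NormalizedMatrix:
    """Tags per million: count / total clean reads * 1e6."""
    total = counts.samples["total_clean_reads"]
    zero = [s for s in total.index if total[s] <= 0]
    if zero:
        raise InputError(f"zero total clean reads for samples: {zero}")
    vals = counts.counts.to_numpy(dtype=float) / total.to_numpy(dtype=float)[None, :] * 1e6
    df = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    return NormalizedMatrix(df, "TPM", counts.samples)


def compute_cpm(counts: CountMatrix) -> NormalizedMatrix:
    """Counts per million of the column sum; column sums are exactly 1e6."""
    colsums = counts.library_sizes
    zero = [s for s in colsums.index if colsums[s] <= 0]
    if zero:
        raise InputError(f"zero column count sum for samples: {zero}")
    vals = counts.counts.to_numpy(dtype=float) / colsums.to_numpy(dtype=float)[None, :] * 1e6
    df = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    return NormalizedMatrix(df, "CPM", counts.samples)


def filter_expressed(
    values: NormalizedMatrix,
    threshold: float = 1.0,
    min_samples: int = 1,
    mode: str = "ge",
) -> set[str]:
    """Features whose value meets the threshold in at least ``min_samples`` samples.

    ``mode='ge'`` keeps features with value >= threshold (the RPKM >= 1
    convention); ``mode='gt'`` keeps value > threshold (the "above 1
    CPM/TPM" convention).
    """
    if min_samples < 1:
        raise InputError("min_samples must be >= 1")
    if mode not in {"ge", "gt"}:
        raise InputError(f"mode must be 'ge' or 'gt', got {mode!r}")
    vals = values.values.to_numpy()
    hits = vals >= threshold if mode == "ge" else vals > threshold
    keep = hits.sum(axis=1) >= min_samples
    return set(values.values.index[keep])
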