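"""Region-level ChIP-seq signal normalization and fold changes.

Works from a region-by-sample read-count matrix (read counting itself is
upstream).  Counts are first depth-normalized to reads per million (RPM),
then each sample is rescaled by its mean RPM over a reference region set —
either the antibody's overlapping peaks (``peak_mean``) or designated
background control regions (``control_mean``, used when every peak region
is itself targeted).  Fold change is the ratio of a region's normalized
signal in a targeted sample to the same region in a non-targeted control.
All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "CountMatrix",
    "depth_normalize",
    "reference_normalize",
    "fold_change_vs_control",
]

BED_COLUMNS = ["chrom", "start", "end", "name"]


class RegionSet:
    """Named genomic intervals, 0-based half-open, unique names."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in BED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"RegionSet missing columns: {missing}")
        frame = frame.reset_index(drop=True)
        if (frame["start"] >= frame["end"]).any():
            bad = frame[frame["start"] >= frame["end"]]["name"].tolist()
            raise ValueError(f"regions with start >= end: {bad}")
        if frame["name"].duplicated().any():
            dup = frame["name"][frame["name"].duplicated()].tolist()
            raise ValueError(f"duplicate region names: {dup}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> list[str]:
        return self.frame["name"].tolist()

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        frame = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2, 3], names=BED_COLUMNS,
        )
        return cls(frame)

    def to_bed(self, path) -> None:
        self.frame[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


class CountMatrix:
    """Read counts per region (rows) and sample (columns), with library sizes."""

    def __init__(self, counts: pd.DataFrame, library_size: pd.Series):
        counts = counts.astype(float)
        if (counts < 0).any().any():
            raise ValueError("counts must be nonnegative")
        missing = [s for s in counts.columns if s not in library_size.index]
        if missing:
            raise ValueError(f"library sizes missing for samples: {missing}")
        self.counts = counts
        self.library_size = library_size.loc[counts.columns].astype(float)

    @classmethod
    def from_tsv(cls, counts_path, library_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lib = pd.read_csv(
            library_path, sep="\t", header=None, names=["sample", "library_size"]
        ).set_index("sample")["library_size"]
        return cls(counts, lib)


def depth_normalize(matrix: CountMatrix) -> pd.DataFrame:
    """Reads per million: counts * 1e6 / library size, per sample."""
    if (matrix.library_size <= 0).any():
        bad = matrix.library_size[matrix.library_size <= 0].index.tolist()
        raise ValueError(f"nonpositive library size for samples: {bad}")
    return matrix.counts * 1e6 / matrix.library_size


def reference_normalize(
    signal: pd.DataFrame,
    reference_regions: RegionSet | list[str],
    method: str = "control_mean",
) -> pd.DataFrame:
    """Divide each sample by its mean signal over the reference regions.

    ``method`` records intent only: ``peak_mean`` when the reference set is
    the antibody's overlapping peaks, ``control_mean`` when it is background
    control regions.  The arithmetic is identical; after normalization each
    sample averages to 1 over its own reference set.
    """
    if method not in ("peak_mean", "control_mean"):
        raise ValueError(f"method must be 'peak_mean' or 'control_mean', got {method!r}")
    names = reference_regions.names if isinstance(reference_regions, RegionSet) else list(reference_regions)
    missing = [n for n in names if n not in signal.index]
    if missing:
        raise ValueError(f"reference regions absent from signal matrix: {missing}")
    ref_mean = signal.loc[names].mean(axis=0)
    if (ref_mean <= 0).any():
        bad = ref_mean[ref_mean <= 0].index.tolist()
        raise ValueError(f"reference mean is zero for samples: {bad}")
    return signal / ref_mean


def fold_change_vs_control(
    normalized: pd.DataFrame,
    targeted_sample: str,
    control_sample: str,
    region: str,
    pseudocount: float = 0.0,
) -> float:
    """Ratio of a region's normalized signal, targeted vs non-targeted control."""
    for sample in (targeted_sample, control_sample):
        if sample not in normalized.columns:
            raise KeyError(f"sample {sample!r} not in matrix")
    if region not in normalized.index:
        raise KeyError(f"region {region!r} not in matrix")
    num = normalized.loc[region, targeted_sample] + pseudocount
    den = normalized.loc[region, control_sample] + pseudocount
    if den == 0:
        raise ZeroDivisionError(
            f"control signal at {region!r} is zero; pass pseudocount > 0 to regularise"
        )
    return float(num / den)
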