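"""Matrix quality control: log2 transform, outlier samples, presence filter,
gene-level aggregation.

The rules follow common label-free proteomics practice: samples whose median
abundance deviates more than k standard deviations from the cohort median are
flagged (and a subject flagged in every tissue it appears in is "consistent",
i.e. recommended for exclusion); proteins must be observed in at least 80% of
a tissue's samples to survive; protein rows mapping to the same gene are
averaged within samples over observed values only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import IntensityMatrix

__all__ = [
    "QcReport",
    "log2_transform",
    "detect_outlier_samples",
    "consistent_outlier_subjects",
    "presence_filter",
    "aggregate_gene_duplicates",
]


@dataclass
class QcReport:
    """What QC removed and why."""

    sample_scores: dict[str, float] = field(default_factory=dict)
    excluded_samples: list[str] = field(default_factory=list)
    proteins_before: int | None = None
    proteins_after: int | None = None
    aggregation_map: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sample_scores": self.sample_scores,
                    "excluded_samples": self.excluded_samples,
                    "proteins_before": self.proteins_before,
                    "proteins_after": self.proteins_after,
                    "aggregation_map": self.aggregation_map,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """log2 of a raw-scale matrix; the missingness mask is unchanged."""
    if m.scale != "raw":
        raise ValueError("log2_transform requires a raw-scale matrix")
    values = m.values.to_numpy()
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "nonpositive intensity at "
            f"protein {m.protein_ids[i]!r}, sample {m.sample_ids[j]!r}"
        )
    out = pd.DataFrame(np.log2(values), index=m.values.index, columns=m.values.columns)
    return IntensityMatrix(out, tissue=m.tissue, scale="log2")


def detect_outlier_samples(m: IntensityMatrix, k: float = 3.0) -> QcReport:
    """Flag samples whose median observed log2 value deviates > k SD.

    Per-sample score d_s = (median_s - M) / SD_(-s) where M is the median of
    the per-sample medians and SD_(-s) the (n-1) standard deviation of the
    *other* samples' medians. The leave-one-out scale keeps a single extreme
    sample from masking itself by inflating the spread it is judged against.
    SD_(-s) = 0 (remaining medians all equal) degenerates to score 0.
    """
    if m.n_samples < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    medians = m.values.median(axis=0, skipna=True)
    center = float(medians.median())
    vals = medians.to_numpy(dtype=float)
    scores_arr = np.zeros(len(vals))
    for i in range(len(vals)):
        sd = float(np.std(np.delete(vals, i), ddof=1))
        if sd > 0:
            scores_arr[i] = (vals[i] - center) / sd
    scores = pd.Series(scores_arr, index=medians.index)
    flagged = scores.index[scores.abs() > k].tolist()
    return QcReport(
        sample_scores={str(s): float(v) for s, v in scores.items()},
        excluded_samples=[str(s) for s in flagged],
    )


def consistent_outlier_subjects(
    reports: Mapping[str, QcReport], subject_of: Mapping[str, str]
) -> list[str]:
    """Subjects flagged in *every* tissue where they have a sample.

    ``subject_of`` maps sample id -> subject id across all tissues.
    """
    flagged_by_subject: dict[str, list[bool]] = {}
    for report in reports.values():
        excluded = set(report.excluded_samples)
        for sample in report.sample_scores:
            subject = subject_of[sample]
            flagged_by_subject.setdefault(subject, []).append(sample in excluded)
    return sorted(s for s, flags in flagged_by_subject.items() if flags and all(flags))


def presence_filter(
    m: IntensityMatrix, min_frac: float = 0.8
) -> tuple[IntensityMatrix, QcReport]:
    """Keep proteins observed in at least ``min_frac`` of the samples.

    The boundary is inclusive: observed_count / n_samples >= min_frac keeps
    the protein (8 of 10 samples passes the default 80% rule). Row order is
    preserved.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    if m.n_proteins == 0 or m.n_samples == 0:
        raise ValueError("presence filter on an empty matrix")
    frac = m.mask.sum(axis=1) / m.n_samples
    keep = frac >= min_frac
    out = IntensityMatrix(m.values.loc[keep], tissue=m.tissue, scale=m.scale)
    report = QcReport(proteins_before=m.n_proteins, proteins_after=int(keep.sum()))
    return out, report


def aggregate_gene_duplicates(
    m: IntensityMatrix, gene_of: Mapping[str, str]
) -> IntensityMatrix:
    """Average protein rows mapping to the same gene, within samples.

    The mean is over observed values only; a cell is missing iff every
    contributing protein is missing in that sample. Row order follows the
    first appearance of each gene.
    """
    missing = [str(p) for p in m.protein_ids if str(p) not in gene_of]
    if missing:
        raise ValueError(f"unmapped protein ids: {missing[:10]}")
    genes = pd.Series([gene_of[str(p)] for p in m.protein_ids], index=m.protein_ids)
    # groupby(sort=False) keeps first-appearance order; mean skips NaN and
    # yields NaN only when every contributing value is NaN
    agg = m.values.groupby(genes.to_numpy(), sort=False).mean()
    agg.index.name = "protein_id"
    return IntensityMatrix(agg, tissue=m.tissue, scale=m.scale)
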