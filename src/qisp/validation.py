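"""Validity screening and replicate concordance of QISPs.

A radial profile is biologically plausible for the differentiating
excitatory-neuron lineage only if its signal is not concentrated in the
deepest ventricular bins: intermediate precursors themselves already show
little signal in sROIs 1-2 and stronger signal superficially.  The *deep
ratio* — mean density over sROIs 1-2 divided by mean density over sROIs
3-20 — captures this; a profile whose ratio strictly exceeds 1.0 is flagged
invalid (VZ-dominant, inconsistent with the lineage).

Replicate concordance quantifies how reproducible the densitometry is when
the ROI is re-placed on the same or nearby sections: all pairwise Pearson
correlations over the 20 bins, plus the spread of peak positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .extraction import N_SROIS, QISP

__all__ = [
    "ValidationReport",
    "ConcordanceReport",
    "deep_ratio",
    "validate_qisps",
    "replicate_concordance",
]

#: number of ventricular bins in the deep-ratio numerator
DEEP_BINS = 2

#: floating guard on the strict ratio boundary: a constant profile's two bin
#: means can differ by ~1e-16 relative, which must not flip its validity
_RATIO_TOL = 1e-9


@dataclass(frozen=True)
class ValidationReport:
    gene_id: str
    deep_ratio: float  # NaN when undefined
    valid: bool
    reason: str = ""


@dataclass
class ConcordanceReport:
    """Pairwise agreement of replicate QISP measurements.

    ``pairwise_r`` is symmetric with unit diagonal; entries are NaN when a
    replicate has zero variance.  Summary statistics are taken over the
    defined upper-triangle entries only.  ``peak_srois`` holds 1-based argmax
    bins; ``max_peak_deviation`` the largest pairwise |difference|.
    """

    pairwise_r: np.ndarray
    r_min: float
    r_max: float
    r_mean: float
    peak_srois: list[int]
    max_peak_deviation: int

    def to_frame(self) -> pd.DataFrame:
        n = self.pairwise_r.shape[0]
        names = [f"rep{i+1}" for i in range(n)]
        return pd.DataFrame(self.pairwise_r, index=names, columns=names)


def _profile(q: "QISP | Sequence[float]", variant: str) -> np.ndarray:
    if isinstance(q, QISP):
        return q.profile(variant)
    p = np.asarray(q, dtype=float)
    if p.shape != (N_SROIS,):
        raise ValueError(f"profile must have length {N_SROIS}")
    return p


def deep_ratio(
    qisp: "QISP | Sequence[float]", variant: str = "smoothed"
) -> float:
    """mean(sROIs 1-2) / mean(sROIs 3-20) of the chosen profile variant.

    Returns NaN when the superficial mean is zero (no signal outside the deep
    VZ); callers treat that as invalid.  The ratio is invariant to positive
    rescaling of the profile.
    """
    p = _profile(qisp, variant)
    deep = p[:DEEP_BINS].mean()
    superficial = p[DEEP_BINS:].mean()
    if superficial == 0.0:
        return float("nan")
    return float(deep / superficial)


def validate_qisps(
    qisps: Sequence[QISP], variant: str = "smoothed"
) -> tuple[list[ValidationReport], list[QISP]]:
    """Flag VZ-dominant profiles and return the retained (valid) QISPs.

    A gene is retained iff its deep ratio is defined and <= 1.0; a ratio of
    exactly 1.0 (uniform profile) is *not* "exceeded" and remains valid.
    Undefined ratios (zero superficial signal) are flagged invalid rather
    than raised.
    """
    reports: list[ValidationReport] = []
    retained: list[QISP] = []
    for q in qisps:
        r = deep_ratio(q, variant)
        if np.isnan(r):
            reports.append(
                ValidationReport(q.gene_id, r, False, "no superficial signal")
            )
        elif r > 1.0 + _RATIO_TOL:
            reports.append(
                ValidationReport(q.gene_id, r, False, "deep ratio exceeds 1.0")
            )
        else:
            reports.append(ValidationReport(q.gene_id, r, True))
            retained.append(q)
    return reports, retained


def reports_to_frame(reports: Sequence[ValidationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in reports],
            "deep_ratio": [r.deep_ratio for r in reports],
            "valid": [r.valid for r in reports],
            "reason": [r.reason for r in reports],
        }
    )


def replicate_concordance(
    qisps: Sequence["QISP | Sequence[float]"], variant: str = "smoothed"
) -> ConcordanceReport:
    """Pairwise Pearson correlation and peak agreement of replicates.

    Replicates with zero variance across the 20 bins have undefined
    correlations; those entries are reported as NaN, excluded from the
    summary statistics, and a warning is emitted.
    """
    if len(qisps) < 2:
        raise ValueError("need at least 2 replicates")
    profiles = np.vstack([_profile(q, variant) for q in qisps])
    n = profiles.shape[0]

    # exact range test: std of a constant vector carries ~1e-16 rounding
    degenerate = np.ptp(profiles, axis=1) == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} replicate(s) have zero variance; "
            "their correlations are undefined and excluded",
            stacklevel=2,
        )
    r = np.full((n, n), np.nan)
    ok = ~degenerate
    if ok.sum() >= 2:
        r_ok = np.corrcoef(profiles[ok])
        r[np.ix_(ok, ok)] = r_ok
    np.fill_diagonal(r, 1.0)

    iu = np.triu_indices(n, k=1)
    upper = r[iu]
    defined = upper[~np.isnan(upper)]
    if defined.size == 0:
        r_min = r_max = r_mean = float("nan")
    else:
        r_min, r_max, r_mean = (
            float(defined.min()),
            float(defined.max()),
            float(defined.mean()),
        )

    peaks = [int(np.argmax(p)) + 1 for p in profiles]
    max_dev = int(max(abs(a - b) for a in peaks for b in peaks))
    return ConcordanceReport(
        pairwise_r=r,
        r_min=r_min,
        r_max=r_max,
        r_mean=r_mean,
        peak_srois=peaks,
        max_peak_deviation=max_dev,
    )
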