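"""Evaluation statistics for positioning performance and flow measurements.

Covers the quantitative evaluation of an automatic-positioning study:

* blood flux from a phase-contrast velocity map (sum over an ROI);
* inter-session coefficient of variation (CoV) between two replicates;
* Bland–Altman agreement on log-transformed measurements, reported as the
  geometric mean ratio and 1.96·SD limits of agreement;
* Pearson chi-square tests of independence on success contingency tables;
* subject- and artery-level success-rate accounting.

CoV convention: with only two replicates, ``100 * |F1 - F2| / mean(F1, F2)``.
Note the alternative convention SD/mean of the pair differs by a factor
of sqrt(2); the absolute-difference form is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FluxMeasurement",
    "SessionPair",
    "AgreementReport",
    "SuccessAccounting",
    "compute_flux",
    "intersession_cov",
    "bland_altman_log",
    "chi_square_independence",
    "success_accounting",
]


@dataclass
class FluxMeasurement:
    artery: str
    flux: float  # ml/min
    session: int = 1
    method: str = "automatic"

    def __post_init__(self) -> None:
        if self.flux <= 0:
            raise ValueError("flux must be positive")


@dataclass
class SessionPair:
    first: FluxMeasurement
    second: FluxMeasurement

    def __post_init__(self) -> None:
        if self.first.artery != self.second.artery or self.first.method != self.second.method:
            raise ValueError("session pair must share artery and method")


@dataclass
class AgreementReport:
    """Bland–Altman summary on the log scale."""

    n: int
    mean_log_diff: float
    sd_log_diff: float
    lower_limit: float
    upper_limit: float
    geometric_mean_ratio: float


@dataclass
class SuccessAccounting:
    n_all_successful: int
    n_one_failed: int
    n_all_failed: int
    subjects: int
    arteries_attempted: int
    arteries_successful: int
    artery_rate_pct: float
    subject_rate_pct: float


def compute_flux(velocity_map: np.ndarray, roi: np.ndarray, pixel_area_cm2: float) -> float:
    """Blood flux (ml/min) from a velocity map (cm/s) summed over an ROI.

    flux = sum(v_i) * pixel_area * 60, giving cm^3/min = ml/min.
    """
    velocity_map = np.asarray(velocity_map, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != velocity_map.shape:
        raise ValueError("ROI shape must match the velocity map")
    if not np.any(roi):
        raise ValueError("empty ROI")
    return float(velocity_map[roi].sum() * pixel_area_cm2 * 60.0)


def intersession_cov(pair: SessionPair) -> float:
    """Inter-session CoV (%) of a two-replicate measurement pair."""
    f1, f2 = pair.first.flux, pair.second.flux
    return 100.0 * abs(f1 - f2) / ((f1 + f2) / 2.0)


def cohort_cov(pairs: list[SessionPair]) -> tuple[float, float]:
    """Mean and SD of per-artery inter-session CoV across a cohort."""
    covs = np.array([intersession_cov(p) for p in pairs])
    return float(covs.mean()), float(covs.std(ddof=1)) if len(covs) > 1 else 0.0


def bland_altman_log(a, b) -> AgreementReport:
    """Log-scale Bland–Altman agreement between paired positive series.

    Differences ``d_i = ln(a_i) - ln(b_i)``; the limits of agreement are
    ``mean(d) +- 1.96 * SD(d)`` (sample SD); the geometric mean ratio is
    ``exp(mean(d))`` — the multiplicative bias of method a over method b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("need n >= 2 pairs")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("measurements must be positive for the log transform")
    d = np.log(a) - np.log(b)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        n=len(d),
        mean_log_diff=mean,
        sd_log_diff=sd,
        lower_limit=mean - 1.96 * sd,
        upper_limit=mean + 1.96 * sd,
        geometric_mean_ratio=float(np.exp(mean)),
    )


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns ``(statistic, dof, p)`` for an r x c contingency table of
    non-negative counts with positive row and column totals.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column total")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def success_accounting(
    n_all_successful: int, n_one_failed: int, n_all_failed: int
) -> SuccessAccounting:
    """Success rates from subject counts in the three performance groups.

    Each subject contributes four arteries; all-successful subjects
    contribute 4 successes, one-artery-failed subjects 3, all-failed 0.
    Rates are exact percentages (round for display).
    """
    for n in (n_all_successful, n_one_failed, n_all_failed):
        if n < 0 or int(n) != n:
            raise ValueError("group counts must be non-negative integers")
    subjects = n_all_successful + n_one_failed + n_all_failed
    attempted = 4 * subjects
    successes = 4 * n_all_successful + 3 * n_one_failed
    return SuccessAccounting(
        n_all_successful=n_all_successful,
        n_one_failed=n_one_failed,
        n_all_failed=n_all_failed,
        subjects=subjects,
        arteries_attempted=attempted,
        arteries_successful=successes,
        artery_rate_pct=100.0 * successes / attempted if attempted else 0.0,
        subject_rate_pct=100.0 * n_all_successful / subjects if subjects else 0.0,
    )
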