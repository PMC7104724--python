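"""Sample-eligibility checks and evaluation statistics.

Under uniform random sequencing (Lander-Waterman), the expected fraction of
zero-coverage positions at average coverage a is f_hat = exp(-a).  A sample
whose observed zero fraction f deviates far above that expectation carries
non-random (noisy or concentrated) coverage and is excluded from growth
estimation.  The rule, applied only below 5x average coverage, flags samples
with log(f) > 0.56 * log(f_hat) — both logs are negative, so this catches
substantially MORE zero coverage than random sampling predicts.  Separately,
fitted pPTR >= 3.0 marks residual noise.

Also here: the absolute relative error used for robustness comparisons
(with its 15% reference threshold), log2 growth rates from abundance time
series, and the lag-scanned Pearson correlation between growth estimates
and experimental rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import CoverageTrack

LOW_COVERAGE_CUTOFF = 5.0
LW_LOG_MULTIPLIER = 0.56
PPTR_CAP = 3.0
ERROR_RATE_THRESHOLD = 0.15


@dataclass
class QCReport:
    """Coverage-eligibility summary of one sample."""

    sample_id: str
    avg_coverage: float
    zero_fraction: float
    theoretical_fraction: float
    log_ratio: float | None  # log(f) / log(f_hat); None when f == 0
    noise_fail: bool
    pptr: float | None = None
    pptr_cap_fail: bool = False

    @property
    def passed(self) -> bool:
        return not (self.noise_fail or self.pptr_cap_fail)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "avg_coverage": self.avg_coverage,
            "zero_fraction": self.zero_fraction,
            "theoretical_fraction": self.theoretical_fraction,
            "log_ratio": self.log_ratio,
            "noise_fail": self.noise_fail,
            "pptr": self.pptr,
            "pptr_cap_fail": self.pptr_cap_fail,
            "passed": self.passed,
        }


def lander_waterman_check(track: CoverageTrack, pptr: float | None = None,
                          multiplier: float = LW_LOG_MULTIPLIER,
                          on_log_scale: bool = True) -> QCReport:
    """Zero-coverage QC on a preprocessed (binned) track.

    ``on_log_scale=True`` applies the threshold as log(f) > m * log(f_hat)
    (the default reading); ``on_log_scale=False`` applies the multiplier to
    the raw theoretical score instead, f > m * f_hat, for sensitivity
    analysis of the ambiguous operand.
    """
    d = np.asarray(track.depths, dtype=float)
    a = float(d.mean())
    f = float(np.mean(d == 0))
    f_hat = math.exp(-a)
    noise_fail = False
    log_ratio = None
    if f > 0:
        log_ratio = math.log(f) / math.log(f_hat) if a > 0 else None
        if a < LOW_COVERAGE_CUTOFF:
            if on_log_scale:
                noise_fail = math.log(f) > multiplier * math.log(f_hat)
            else:
                noise_fail = f > multiplier * f_hat
    # f == 0 with low coverage: no zero bins at all -> passes the noise rule
    cap_fail = pptr is not None and pptr >= PPTR_CAP
    return QCReport(
        sample_id=track.sample_id,
        avg_coverage=a,
        zero_fraction=f,
        theoretical_fraction=f_hat,
        log_ratio=log_ratio,
        noise_fail=bool(noise_fail),
        pptr=pptr,
        pptr_cap_fail=bool(cap_fail),
    )


def error_rate(estimate, reference):
    """Absolute relative error |(estimate - reference) / reference|.

    Vectorizes over array inputs; the reference must be non-zero.
    """
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if np.any(ref == 0):
        raise ValueError("reference estimate must be non-zero")
    out = np.abs((est - ref) / ref)
    return float(out) if out.ndim == 0 else out


def within_threshold(err, threshold: float = ERROR_RATE_THRESHOLD):
    """Whether an error rate is at or below the acceptance threshold (15%)."""
    return np.asarray(err) <= threshold


def growth_rate_from_abundance(abundance, times, mode: str = "centered") -> np.ndarray:
    """Per-time log2 growth rates from an abundance time series.

    centered: gr_i = (log2 a_{i+1} - log2 a_{i-1}) / (t_{i+1} - t_{i-1})
    (endpoints omitted); forward: gr_i = (log2 a_{i+1} - log2 a_i) /
    (t_{i+1} - t_i).
    """
    a = np.asarray(abundance, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.any(a <= 0):
        raise ValueError("abundances must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    la = np.log2(a)
    if mode == "centered":
        return (la[2:] - la[:-2]) / (t[2:] - t[:-2])
    if mode == "forward":
        return (la[1:] - la[:-1]) / (t[1:] - t[:-1])
    raise ValueError(f"unknown mode {mode!r}")


def lagged_correlation(estimates, growth_rates, lag_grid, min_pairs: int = 3):
    """Best time delay between growth estimates and experimental rates.

    Both series must live on the same integer-index grid; for each lag in
    ``lag_grid`` the estimate series is shifted by that many steps and the
    Pearson correlation is computed over the overlapping points.  Lags with
    fewer than ``min_pairs`` overlapping pairs are rejected.  Returns
    (best_lag, best_r, {lag: r}).
    """
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(growth_rates, dtype=float)
    results = {}
    for lag in lag_grid:
        lag = int(lag)
        if lag >= 0:
            xi, yi = x[lag:], y[: y.size - lag] if lag else y
        else:
            xi, yi = x[:lag], y[-lag:]
        n = min(xi.size, yi.size)
        xi, yi = xi[:n], yi[:n]
        ok = np.isfinite(xi) & np.isfinite(yi)
        if ok.sum() < min_pairs:
            continue
        r, _ = stats.pearsonr(xi[ok], yi[ok])
        results[lag] = float(r)
    if not results:
        raise ValueError("no lag yields the minimum number of overlapping pairs")
    best = max(results, key=lambda k: results[k])
    return best, results[best], results
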