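"""Statistics over distance series and the semi-quantitative discriminant calls.

The discriminant is the mean per-frame distance between a ligand's reactive
atom and the heme iron: probe substrates sit close to the iron (≈0.41–0.44 nm
stationary means), minor substrates somewhat further (≈0.50 nm), and poorly
or non-metabolised complexes further still or detached (≥0.6 nm, up to
≈1.16 nm). This module provides

* :func:`summarize` — mean ± SE over frames (naive SD/√n by default, matching
  the conventional reporting of MD frame statistics; an effective-sample-size
  correction for autocorrelated frames is available as a flag),
* :func:`compare` — independent two-sample t-test (pooled-variance Student by
  default, Welch as an option) between two complexes' distance series,
* :func:`detect_detachment` — first sustained excursion above a threshold,
* :func:`call_substrate` / :func:`call_variant_effect` — the semi-quantitative
  labels the pipeline exists to produce.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry_engine import DistanceSeries

logger = logging.getLogger(__name__)

#: Default sustained-distance threshold (nm) for detachment calls.
DETACHMENT_THRESHOLD_NM = 0.6
#: Default persistence window (ps) an excursion must last to count as detachment.
DETACHMENT_WINDOW_PS = 1000.0
#: Margin (nm) above the probe envelope within which a mean is probe-like.
PROBE_MARGIN_NM = 0.05
#: Margin (nm) above the probe envelope within which a mean is minor-substrate-like.
MINOR_MARGIN_NM = 0.15


@dataclass(frozen=True)
class SeriesSummary:
    mean_nm: float
    se_nm: float
    sd_nm: float
    n_frames: int
    label: str = ""


@dataclass(frozen=True)
class ComparisonResult:
    t_stat: float
    df: float
    p_value: float
    alpha: float
    significant: bool
    direction: str  # A_lower | B_lower | none


@dataclass(frozen=True)
class DetachmentEvent:
    onset_ps: float | None
    threshold_nm: float
    window_ps: float

    @property
    def detected(self) -> bool:
        return self.onset_ps is not None


@dataclass(frozen=True)
class SubstrateCall:
    label: str  # probe_like | minor_substrate | poor_or_non_substrate
    mean_nm: float
    probe_envelope_nm: float


@dataclass(frozen=True)
class VariantEffectCall:
    label: str  # likely_enhanced | likely_reduced | unchanged
    delta_nm: float  # variant mean − reference mean
    comparison: ComparisonResult


def _ess(values: np.ndarray) -> float:
    """Effective sample size from the integrated autocorrelation time.

    Uses the initial-positive-sequence estimator: lagged autocorrelations are
    summed until the first non-positive term (or n/3 lags).
    """
    n = values.size
    x = values - values.mean()
    var = float(np.dot(x, x)) / n
    if var == 0.0:
        return float(n)
    acf_sum = 0.0
    for lag in range(1, n // 3):
        rho = float(np.dot(x[:-lag], x[lag:])) / (n * var)
        if rho <= 0.0:
            break
        acf_sum += rho
    return n / (1.0 + 2.0 * acf_sum)


def summarize(s: DistanceSeries, ess_correction: bool = False) -> SeriesSummary:
    """Mean, sample SD and SE of a distance series over all frames.

    By default frames are treated as independent (SE = SD/√n), the convention
    under which MD frame statistics such as "0.439 ± 0.002 nm over 5000
    frames" are reported. With ``ess_correction`` the SE is rescaled by the
    effective sample size estimated from the series' autocorrelation time,
    which is the statistically honest choice for correlated frames.
    """
    v = s.values_nm
    n = v.size
    if n < 2:
        raise ValueError("summarize requires at least 2 frames")
    sd = float(np.std(v, ddof=1))
    n_eff = _ess(v) if ess_correction else float(n)
    return SeriesSummary(
        mean_nm=float(np.mean(v)),
        se_nm=sd / math.sqrt(n_eff),
        sd_nm=sd,
        n_frames=n,
        label=s.label,
    )


def compare(
    a: DistanceSeries,
    b: DistanceSeries,
    alpha: float = 0.05,
    mode: str = "student",
    ess_correction: bool = False,
) -> ComparisonResult:
    """Independent two-sample t-test between the per-frame values of two series.

    ``student`` pools the variances (df = nA + nB − 2); ``welch`` uses the
    Satterthwaite approximation. p-values are two-sided; the direction is the
    sign of the mean difference and is reported only when significant.

    Frames of an MD-like series are autocorrelated, which the frame-wise test
    ignores (its type-I rate inflates accordingly). With ``ess_correction``
    each series' variance contribution is scaled by its effective sample
    size (Welch-style combination), restoring an approximately calibrated
    test for mean-reverting series.

    Degenerate contract: two constant series with equal means give t = 0,
    p = 1; constant series with different means give p = 0.
    """
    if mode not in ("student", "welch"):
        raise ValueError(f"mode must be 'student' or 'welch', got {mode!r}")
    va, vb = a.values_nm, b.values_nm
    if va.size < 2 or vb.size < 2:
        raise ValueError("compare requires at least 2 frames per series")
    mean_a, mean_b = float(np.mean(va)), float(np.mean(vb))
    if np.std(va, ddof=1) == 0.0 and np.std(vb, ddof=1) == 0.0:
        df = float(va.size + vb.size - 2)
        if mean_a == mean_b:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.copysign(math.inf, mean_a - mean_b)
            p = 0.0
    elif ess_correction:
        na_eff, nb_eff = _ess(va), _ess(vb)
        sa2 = float(np.var(va, ddof=1)) / na_eff
        sb2 = float(np.var(vb, ddof=1)) / nb_eff
        t_stat = (mean_a - mean_b) / math.sqrt(sa2 + sb2)
        df = (sa2 + sb2) ** 2 / (
            sa2**2 / (na_eff - 1) + sb2**2 / (nb_eff - 1)
        )
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    else:
        res = stats.ttest_ind(va, vb, equal_var=(mode == "student"))
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    significant = p < alpha
    if not significant:
        direction = "none"
    else:
        direction = "A_lower" if mean_a < mean_b else "B_lower"
    return ComparisonResult(
        t_stat=t_stat, df=df, p_value=p, alpha=alpha,
        significant=significant, direction=direction,
    )


def detect_detachment(
    s: DistanceSeries,
    threshold_nm: float = DETACHMENT_THRESHOLD_NM,
    window_ps: float = DETACHMENT_WINDOW_PS,
) -> DetachmentEvent:
    """First sustained excursion of the distance above a threshold.

    The onset is the start time of the first run of consecutive frames, of
    duration ≥ ``window_ps``, all strictly above ``threshold_nm`` — the
    operational definition of the ligand detaching from a catalytically
    competent pose. Returns an event with ``onset_ps=None`` when no such run
    exists.
    """
    if s.n_frames < 2:
        raise ValueError("series too short for detachment detection")
    dt = s.dt_ps()
    span = float(s.times_ps[-1] - s.times_ps[0])
    if window_ps > span:
        raise ValueError(
            f"persistence window {window_ps} ps exceeds series span {span} ps"
        )
    needed = max(1, int(math.ceil(window_ps / dt - 1e-9)))
    above = s.values_nm > threshold_nm
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= needed:
            start = i - needed + 1
            return DetachmentEvent(
                onset_ps=float(s.times_ps[start]),
                threshold_nm=threshold_nm,
                window_ps=window_ps,
            )
    return DetachmentEvent(onset_ps=None, threshold_nm=threshold_nm, window_ps=window_ps)


def call_substrate(
    summary: SeriesSummary,
    probe_means_nm: list[float],
    probe_margin_nm: float = PROBE_MARGIN_NM,
    minor_margin_nm: float = MINOR_MARGIN_NM,
) -> SubstrateCall:
    """Semi-quantitative substrate-likelihood call against the probe envelope.

    The envelope is the largest mean distance among the probe substrates.
    Means within ``probe_margin_nm`` of the envelope are probe-like; within
    ``minor_margin_nm``, minor substrates; beyond that, poorly or not
    metabolised.
    """
    if not probe_means_nm:
        raise ValueError("probe_means_nm must be non-empty")
    if minor_margin_nm < probe_margin_nm:
        raise ValueError("minor_margin_nm must be >= probe_margin_nm")
    envelope = float(max(probe_means_nm))
    m = summary.mean_nm
    if m <= envelope + probe_margin_nm:
        label = "probe_like"
    elif m <= envelope + minor_margin_nm:
        label = "minor_substrate"
    else:
        label = "poor_or_non_substrate"
    return SubstrateCall(label=label, mean_nm=m, probe_envelope_nm=envelope)


def call_variant_effect(
    variant: DistanceSeries,
    reference: DistanceSeries,
    alpha: float = 0.05,
    mode: str = "student",
) -> VariantEffectCall:
    """Compare a variant complex's distance series with the reference allele's.

    A significantly *lower* mean distance in the variant is read as a likely
    enhancement of metabolism (the reactive atom sits closer to the iron); a
    significantly higher mean as a likely reduction; otherwise unchanged.
    """
    cmp = compare(variant, reference, alpha=alpha, mode=mode)
    delta = float(np.mean(variant.values_nm) - np.mean(reference.values_nm))
    if not cmp.significant:
        label = "unchanged"
    elif delta < 0:
        label = "likely_enhanced"
    else:
        label = "likely_reduced"
    return VariantEffectCall(label=label, delta_nm=delta, comparison=cmp)


def batch_means_se(values: np.ndarray, n_batches: int = 50) -> float:
    """Batch-means standard error of the sample mean of a correlated series.

    The series is cut into ``n_batches`` contiguous batches; the SE is the
    standard deviation of batch means divided by √n_batches. With batch
    lengths well beyond the autocorrelation time this is a consistent SE for
    autocorrelated (e.g. OU-like) frame series.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 * n_batches:
        raise ValueError("series too short for the requested number of batches")
    usable = (values.size // n_batches) * n_batches
    batches = values[:usable].reshape(n_batches, -1)
    bm = batches.mean(axis=1)
    return float(np.std(bm, ddof=1) / math.sqrt(n_batches))
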