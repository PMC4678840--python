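"""Time-course aggregation, onset estimation and loading-order summaries.

Onsets (restriction-point passage, MCM loading, S entry) are read off a
fraction-versus-time curve by fitting a logistic

    f(t) = b + A / (1 + exp(-(t - m) / s))

and reporting the time where the fit reaches ``b + 0.10 A``. The 10%-of-
amplitude crossing (rather than the midpoint) matches the "starts from"
reading of a time course: the time when the first cells appear. Confidence
intervals come from a parametric bootstrap of the per-timepoint binomial
counts.

Fits are restricted to the rising window of the series (nadir to peak):
several of the measured curves are non-monotone for good biological reasons
— the RB1-negative fraction starts high because early-G1/G0 cells have
not-yet-phosphorylated, unanchored RB1, and per-quadrant fractions fall again
when a subpopulation exits G1 into S.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import InputError
from .gating import QuadrantResult, SPhaseFraction, wilson_ci

log = logging.getLogger(__name__)


def logistic(t, b, A, m, s):
    return b + A / (1.0 + np.exp(-(t - m) / s))


def _logistic_jac(t, b, A, m, s):
    g = 1.0 / (1.0 + np.exp(-(t - m) / s))
    dg = g * (1.0 - g)
    return np.stack([np.ones_like(t), g, -A * dg / s, -A * dg * (t - m) / (s * s)], axis=1)


@dataclass
class OnsetEstimate:
    """A detected (or not) onset time with a bootstrap CI."""

    detected: bool
    onset: float | None = None
    ci: tuple[float, float] | None = None
    message: str = ""
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.ci is not None:
            d["ci"] = list(self.ci)
        return d


@dataclass
class TimecourseResult:
    """Per-timepoint quadrant fractions and estimated onsets."""

    table: pd.DataFrame
    rp_onset: OnsetEstimate
    mcm_onset: OnsetEstimate
    s_onset: OnsetEstimate

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "onsets": {
                "rp_onset": self.rp_onset.to_dict(),
                "mcm_onset": self.mcm_onset.to_dict(),
                "s_onset": self.s_onset.to_dict(),
            },
        }


@dataclass
class OrderSummary:
    """Loading-order verdict for one snapshot population.

    ``q2_frac`` (MCM+/RB1+: loaded with RB1 still anchored) is the
    conservative lower bound on the fraction of G1 cells that load before the
    restriction point; Q4 is intrinsically ambiguous and is reported but
    never attributed to either side.
    """

    q2_frac: float
    q2_ci: tuple[float, float]
    q1_frac: float
    q1_ci: tuple[float, float]
    q4_frac: float
    q4_ambiguous: bool
    verdict: str
    misclass_floor: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["q2_ci"] = list(self.q2_ci)
        d["q1_ci"] = list(self.q1_ci)
        return d


def _rise_window(frac: np.ndarray) -> slice:
    """Indices of the rising stretch of a series: nadir up to the peak."""
    i0 = int(np.argmin(frac))
    i1 = int(np.argmax(frac))
    if i1 > i0 and i1 - i0 + 1 >= 4:
        return slice(i0, i1 + 1)
    if len(frac) - i0 >= 4:
        return slice(i0, len(frac))
    return slice(0, len(frac))


def _level_crossing(t: np.ndarray, f: np.ndarray, level: float) -> float | None:
    """First upward crossing of ``level`` by the piecewise-linear curve."""
    if f[0] >= level:
        return float(t[0])
    for i in range(len(f) - 1):
        if f[i] < level <= f[i + 1]:
            frac = (level - f[i]) / (f[i + 1] - f[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def estimate_onset(timepoints, fractions, counts=None, n_boot: int = 500,
                   seed: int = 0, onset_level: float = 0.10,
                   min_amplitude: float = 0.05, restrict_rise: bool = True,
                   method: str = "interp") -> OnsetEstimate:
    """Estimate when a fraction-versus-time curve starts to rise.

    The logistic fit supplies baseline, amplitude and the detection decision.
    With ``method="interp"`` (default) the onset is where the
    linearly-interpolated measured curve first crosses
    ``baseline + onset_level * amplitude``; with ``method="fit"`` it is the
    same crossing of the fitted logistic itself, ``m - s*ln(1/level - 1)``.
    The two coincide for well-resolved logistic rises, but the parametric
    crossing is biased by up to half a sampling interval when the whole rise
    falls between two timepoints, so the interpolated crossing is preferred
    on coarse grids.

    ``counts`` are the per-timepoint denominators (used for weighting and
    for the parametric bootstrap; CIs are omitted without them). Returns a
    not-detected result rather than raising on flat series or
    non-convergence.
    """
    if method not in ("interp", "fit"):
        raise InputError(f"unknown onset method {method!r}")
    t = np.asarray(timepoints, dtype=float)
    f = np.asarray(fractions, dtype=float)
    n = None if counts is None else np.asarray(counts, dtype=float)
    keep = np.isfinite(t) & np.isfinite(f)
    if n is not None:
        keep &= np.isfinite(n) & (n > 0)
        n = n[keep]
    t, f = t[keep], f[keep]
    if len(t) < 4:
        raise InputError(f"need >= 4 finite timepoints, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise InputError("timepoints must be strictly increasing")

    win = _rise_window(f) if restrict_rise else slice(0, len(f))
    tw, fw = t[win], f[win]
    nw = None if n is None else n[win]
    spread = float(fw.max() - fw.min())
    if spread < min_amplitude:
        return OnsetEstimate(detected=False, message="amplitude below detection floor")

    fit = _fit_logistic(tw, fw, nw)
    if fit is None:
        return OnsetEstimate(detected=False, message="logistic fit did not converge")
    b, A, m, s = fit
    if A < min_amplitude:
        return OnsetEstimate(detected=False, message="fitted amplitude below detection floor")

    def _onset_from(fvals, params):
        bb, bA, bm, bs = params
        if method == "fit":
            return bm - bs * np.log(1.0 / onset_level - 1.0)
        # the fitted asymptotic amplitude can exceed the observed range when
        # the plateau is not yet sampled; cap the level inside the data
        a_eff = min(bA, max(fvals.max() - bb, 1e-6))
        x = _level_crossing(tw, fvals, bb + onset_level * a_eff)
        return x if x is not None else bm - bs * np.log(1.0 / onset_level - 1.0)

    onset = float(_onset_from(fw, (b, A, m, s)))

    ci = None
    if nw is not None and n_boot > 0:
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        boots = []
        p = np.clip(fw, 0.0, 1.0)
        for _ in range(n_boot):
            fb = rng.binomial(nw.astype(int), p) / nw
            bfit = _fit_logistic(tw, fb, nw)
            if bfit is None or bfit[1] < min_amplitude:
                continue
            boots.append(_onset_from(fb, bfit))
        if len(boots) >= max(20, n_boot // 10):
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci = (min(float(lo), onset), max(float(hi), onset))
    return OnsetEstimate(detected=True, onset=onset, ci=ci,
                         params={"baseline": float(b), "amplitude": float(A),
                                 "midpoint": float(m), "scale": float(s)})


def _fit_logistic(t, f, n):
    t_range = float(t.max() - t.min())
    if t_range <= 0:
        return None
    b0 = float(f.min())
    A0 = max(float(f.max() - f.min()), 1e-3)
    half = b0 + A0 / 2.0
    above = np.nonzero(f >= half)[0]
    m0 = float(t[above[0]]) if len(above) else float(t[len(t) // 2])
    s0 = max(t_range / 10.0, 0.2)
    sigma = None
    if n is not None:
        p = np.clip(f, 1e-4, 1 - 1e-4)
        sigma = np.sqrt(p * (1 - p) / n) + 1e-4
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                logistic, t, f, p0=[b0, A0, m0, s0], sigma=sigma, jac=_logistic_jac,
                bounds=([0.0, 1e-4, t.min() - 2 * t_range, 0.1],
                        [1.0, 1.5, t.max() + 2 * t_range, max(t_range, 0.5)]),
                maxfev=1000)
    except (RuntimeError, ValueError):
        return None
    return tuple(float(x) for x in popt)


def summarize_timecourse(series, n_boot: int = 200, seed: int = 0) -> TimecourseResult:
    """Assemble a time course and estimate the three onsets.

    ``series`` is a list of ``(timepoint, QuadrantResult, SPhaseFraction)``
    tuples (a quadrant entry may be None when a timepoint had no usable G1
    population — for example after the G1 pool has drained into S).
    Derived per-timepoint quantities: ``mcm_positive_frac = q1 + q2``
    (cells that have started loading, wherever they are relative to the
    restriction point) and ``rb1_released_frac = q1 + q4`` (G1 cells whose
    RB1 is not anchored).
    """
    if len(series) < 2:
        raise InputError("need >= 2 timepoints")
    tps = [float(s[0]) for s in series]
    if len(set(tps)) != len(tps):
        raise InputError("duplicate timepoints")
    if any(b <= a for a, b in zip(tps, tps[1:])):
        raise InputError("timepoints must be strictly increasing")

    rows = []
    for tp, qr, sp in series:
        row = {"timepoint": tp}
        if qr is not None:
            row.update(
                n_g1=qr.n_total,
                frac_q1=qr.frac_q1, frac_q2=qr.frac_q2,
                frac_q3=qr.frac_q3, frac_q4=qr.frac_q4,
                ci_q1_lo=qr.ci_q1[0], ci_q1_hi=qr.ci_q1[1],
                ci_q2_lo=qr.ci_q2[0], ci_q2_hi=qr.ci_q2[1],
                ci_q3_lo=qr.ci_q3[0], ci_q3_hi=qr.ci_q3[1],
                ci_q4_lo=qr.ci_q4[0], ci_q4_hi=qr.ci_q4[1],
                mcm_positive_frac=qr.frac_q1 + qr.frac_q2,
                rb1_released_frac=qr.frac_q1 + qr.frac_q4,
            )
        else:
            row.update(n_g1=0)
        if sp is not None:
            row.update(s_phase_frac=sp.fraction, n_singlets=sp.n,
                       s_ci_lo=sp.ci[0], s_ci_hi=sp.ci[1])
        rows.append(row)
    table = pd.DataFrame(rows)

    def _onset(colf, coln):
        if colf not in table.columns:
            return OnsetEstimate(detected=False, message=f"no {colf} data")
        try:
            return estimate_onset(table["timepoint"], table[colf],
                                  counts=table.get(coln), n_boot=n_boot, seed=seed)
        except InputError as exc:
            return OnsetEstimate(detected=False, message=str(exc))

    return TimecourseResult(
        table=table,
        rp_onset=_onset("rb1_released_frac", "n_g1"),
        mcm_onset=_onset("mcm_positive_frac", "n_g1"),
        s_onset=_onset("s_phase_frac", "n_singlets"),
    )


def summarize_order(result: QuadrantResult, misclass_floor: float = 0.02) -> OrderSummary:
    """Classify a snapshot's loading order relative to the restriction point.

    ``loading_before_rp_detected`` requires the lower Wilson bound of the Q2
    fraction to clear the misclassification floor (estimated from
    simulations or controls); ``loading_after_rp_dominant`` requires loading
    to be present (Q1 clearly above the floor) while Q2 is at or below it;
    anything else is ``mixed``.
    """
    if not 0.0 <= misclass_floor <= 1.0:
        raise InputError("misclass_floor must be in [0, 1]")
    if result.ci_q2[0] > misclass_floor:
        verdict = "loading_before_rp_detected"
    elif result.frac_q2 <= misclass_floor and result.ci_q1[0] > misclass_floor:
        verdict = "loading_after_rp_dominant"
    else:
        verdict = "mixed"
    return OrderSummary(
        q2_frac=result.frac_q2, q2_ci=result.ci_q2,
        q1_frac=result.frac_q1, q1_ci=result.ci_q1,
        q4_frac=result.frac_q4, q4_ambiguous=True,
        verdict=verdict, misclass_floor=misclass_floor,
    )
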