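"""Automated gating: singlets, DNA peaks, thresholds and quadrants.

The gating scheme mirrors standard cell-cycle flow-cytometry practice for
pre-extracted samples:

1. single cells are selected on DNA pulse width (area-versus-width
   discrimination; doublets have ~2x area but much wider pulses);
2. the G1 and G2 peaks of the DNA-content histogram are located (G2 is
   constrained to 1.85-2.15x G1 — DNA doubling);
3. the G1 gate keeps only the *left* side of the G1 peak, minimizing
   contamination by early-S cells;
4. the MCM-positivity threshold is the signal of cells at the S/G2 border,
   where MCM offloading is complete (a built-in negative reference);
5. the RB1-positivity threshold splits the anchored G1 population from
   S-phase cells, whose hyper-phosphorylated RB1 was washed out by the
   extraction;
6. G1 events are classified into quadrants Q1 (MCM+/RB1-), Q2 (MCM+/RB1+),
   Q3 (MCM-/RB1+) and Q4 (MCM-/RB1-).

Immunofluorescence channels are analyzed on a log10 scale; the DNA channel on
a linear scale. Gating operations never consume ground-truth columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from statsmodels.stats.proportion import proportion_confint

from .errors import AnalysisError, ConfigurationError, InputError

log = logging.getLogger(__name__)

_LOG_FLOOR = 1e-12


@dataclass
class DnaPeaks:
    """G1 and G2 positions of the DNA-content histogram (linear units)."""

    g1_peak: float
    g2_peak: float
    g2_inferred: bool = False   # no G2 mode found; g2 = 2 * g1 assumed
    g1_ambiguous: bool = False  # single mode with no half/double partner


@dataclass
class GateSet:
    """All derived gates and thresholds for one sample (or pooled samples)."""

    singlet_center: float
    singlet_cut: float
    g1_peak: float
    g2_peak: float
    g1_gate: tuple[float, float]      # [lo, hi) in dna_area units
    s_interval: tuple[float, float]   # exclusive band between G1 and the border
    sg2_border: tuple[float, float]   # late-S window just below the G2 peak
    mcm_threshold: float | None = None
    rb1_threshold: float | None = None
    threshold_mode: str = "population"
    g2_inferred: bool = False
    g1_ambiguous: bool = False
    rb1_fallback: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.g1_gate
        if not lo < hi:
            raise ConfigurationError("g1_gate interval is empty or inverted")
        if hi > self.g1_peak * (1 + 1e-9):
            raise ConfigurationError("g1_gate must end at or left of the G1 peak")
        blo, bhi = self.sg2_border
        if not (self.g1_peak < blo < bhi <= self.g2_peak * 1.02):
            raise ConfigurationError("sg2_border must sit between the G1 and G2 peaks")
        ratio = self.g2_peak / self.g1_peak
        if not 1.85 <= ratio <= 2.15:
            raise ConfigurationError(f"G2/G1 peak ratio {ratio:.3f} outside [1.85, 2.15]")
        slo, shi = self.s_interval
        if not slo < shi:
            raise ConfigurationError("s_interval is empty or inverted")
        for name in ("mcm_threshold", "rb1_threshold"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["g1_gate"] = list(self.g1_gate)
        d["s_interval"] = list(self.s_interval)
        d["sg2_border"] = list(self.sg2_border)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GateSet":
        d = dict(d)
        for key in ("g1_gate", "s_interval", "sg2_border"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class QuadrantResult:
    """Q1-Q4 composition of the gated G1 population with Wilson 95% CIs."""

    n_q1: int
    n_q2: int
    n_q3: int
    n_q4: int
    n_total: int
    frac_q1: float
    frac_q2: float
    frac_q3: float
    frac_q4: float
    ci_q1: tuple[float, float]
    ci_q2: tuple[float, float]
    ci_q3: tuple[float, float]
    ci_q4: tuple[float, float]
    gate_provenance: dict = field(default_factory=dict)
    label: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("ci_q1", "ci_q2", "ci_q3", "ci_q4"):
            d[k] = list(getattr(self, k))
        return d


@dataclass
class SPhaseFraction:
    fraction: float
    ci: tuple[float, float]
    n: int


def _require_measurement_columns(events: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in events.columns]
    if missing:
        raise InputError(f"events table is missing columns {missing}; has {list(events.columns)}")


def wilson_ci(count: int, nobs: int) -> tuple[float, float]:
    if nobs == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    # the analytic Wilson bounds at the extremes are exactly 0 and 1; clamp
    # floating-point dust so the interval always contains the fraction
    lo = 0.0 if count == 0 else float(lo)
    hi = 1.0 if count == nobs else float(hi)
    return (lo, hi)


def gate_singlets(events: pd.DataFrame, k_mad: float = 4.0):
    """Retain single cells by a robust cut on DNA pulse width.

    The rule is ``dna_width <= median + k_mad * MAD`` (MAD scaled to be
    consistent with a normal sd). Returns the retained subset and the
    ``(width_center, width_cut)`` rule. Falls back to a fixed relative cut
    (median * 1.3) with a warning when the width distribution is degenerate.
    """
    if k_mad <= 0:
        raise ConfigurationError("k_mad must be positive")
    _require_measurement_columns(events, ["dna_width"])
    if len(events) < 50:
        raise InputError(f"need >= 50 events for the singlet gate, got {len(events)}")
    w = events["dna_width"].to_numpy()
    center = float(np.median(w))
    mad = float(np.median(np.abs(w - center))) * 1.4826
    if mad <= 0:
        warnings.warn("degenerate dna_width distribution (MAD = 0); "
                      "falling back to a fixed 1.3x relative cut")
        cut = center * 1.3
    else:
        cut = center + k_mad * mad
    keep = w <= cut
    excluded = 1.0 - keep.mean()
    log.info("singlet gate: center=%.3g cut=%.3g excluded=%.2f%%", center, cut, 100 * excluded)
    return events.loc[keep].reset_index(drop=True), (center, float(cut))


def _gauss_on_ramp(x, A, m, s, c0, c1):
    return A * np.exp(-0.5 * ((x - m) / s) ** 2) + c0 + c1 * (x - m)


def _refine_peak(x: np.ndarray, center: float, rel_window: float = 0.10) -> float:
    """Refine a coarse DNA peak as a Gaussian on a linear background.

    The S-phase continuum forms a ramp under both cell-cycle peaks that
    shifts the raw histogram mode (by up to ~2.5% for the G2 peak at 5% CV),
    so the peak is fit as a Gaussian plus a local linear background — the
    same decomposition classical DNA-histogram cell-cycle fits use.
    """
    from scipy.optimize import curve_fit

    sel = x[(x >= center * (1 - rel_window)) & (x <= center * (1 + rel_window))]
    if len(sel) == 0:
        return center
    med = float(np.median(sel))
    if np.mean(np.abs(sel - med) <= 1e-9 * center) > 0.2:
        return med  # degenerate (noise-free) spike
    counts, edges = np.histogram(sel, bins=40)
    mids = 0.5 * (edges[:-1] + edges[1:])
    p0 = [float(counts.max()), center, 0.04 * center, max(float(counts.min()), 1.0), 0.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss_on_ramp, mids, counts.astype(float), p0=p0,
                sigma=np.sqrt(counts + 1.0),
                bounds=([0.0, center * (1 - rel_window), 0.005 * center, 0.0, -np.inf],
                        [np.inf, center * (1 + rel_window), 0.15 * center, np.inf, np.inf]),
                maxfev=2000)
        return float(popt[1])
    except (RuntimeError, ValueError):
        return float(mids[int(np.argmax(counts))])


def find_dna_peaks(events: pd.DataFrame, min_events: int = 200) -> DnaPeaks:
    """Locate the G1 and G2 modes of the DNA-content histogram.

    The dominant mode is first tested for a companion mode at half its
    position (in which case the dominant mode is G2) and then for one at
    about double (the usual case, G2 found directly). A lone mode is taken as
    G1 with ``g2 = 2 * g1`` but flagged ambiguous, since DNA content alone
    cannot distinguish a pure-G1 sample from a pure-G2/M one (for example a
    mitotic-arrest sample at t = 0).
    """
    _require_measurement_columns(events, ["dna_area"])
    x = events["dna_area"].to_numpy()
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < min_events:
        raise InputError(f"need >= {min_events} events to find DNA peaks, got {len(x)}")
    lo, hi = np.percentile(x, [0.5, 99.8])
    if not hi > lo * (1 + 1e-9):
        raise AnalysisError("no identifiable G1 mode in dna_area: degenerate distribution")
    # pad the range so modes sitting at the data extremes (for example a
    # noise-free G1 spike) are interior histogram peaks
    lo, hi = lo * 0.85, hi * 1.10
    counts, edges = np.histogram(x, bins=512, range=(lo, hi))
    sm = gaussian_filter1d(counts.astype(float), 4.0)
    idx, props = find_peaks(sm, prominence=0.03 * sm.max(), height=0.02 * sm.max())
    if len(idx) == 0:
        raise AnalysisError("no identifiable G1 mode in dna_area")
    centers = 0.5 * (edges[idx] + edges[idx + 1])
    heights = props["peak_heights"]
    dom = centers[int(np.argmax(heights))]

    def _partner(lo_ratio, hi_ratio):
        cand = [(h, c) for c, h in zip(centers, heights) if lo_ratio <= c / dom <= hi_ratio]
        return max(cand)[1] if cand else None

    g1c, g2c = dom, None
    half = _partner(0.46, 0.54)
    if half is not None:
        g1c, g2c = half, dom
    else:
        dbl = _partner(1.85, 2.15)
        if dbl is not None:
            g2c = dbl
    g1 = _refine_peak(x, g1c)
    ambiguous = False
    if g2c is not None:
        g2 = _refine_peak(x, g2c)
        if not 1.85 <= g2 / g1 <= 2.15:  # refinement drifted; fall back
            g2, g2c = 2.0 * g1, None
    if g2c is None:
        g2 = 2.0 * g1
        ambiguous = len(idx) == 1
        log.info("no G2 mode found; assuming g2 = 2 * g1 (ambiguous=%s)", ambiguous)
    return DnaPeaks(g1_peak=g1, g2_peak=float(g2), g2_inferred=g2c is None,
                    g1_ambiguous=ambiguous)


def define_gates(events: pd.DataFrame, peaks: DnaPeaks, *,
                 singlet_rule: tuple[float, float] | None = None,
                 w_lo: float = 0.10, w_hi: float = 0.10,
                 border: tuple[float, float] = (0.90, 0.98)) -> GateSet:
    """Build the interval gates from the DNA peaks.

    ``g1_gate = [g1_peak * (1 - w_lo), g1_peak)`` — left side of the peak
    only; ``sg2_border = [border[0], border[1]) * g2_peak`` — late-S window
    excluding the G2 peak itself; ``s_interval`` is the exclusive band in
    between. All intervals are half-open, lower-inclusive.
    """
    if not 0 < w_lo < 1 or not 0 < w_hi < 1:
        raise ConfigurationError("w_lo and w_hi must be in (0, 1)")
    if not 0 < border[0] < border[1] <= 1.02:
        raise ConfigurationError("border fractions must satisfy 0 < lo < hi <= 1.02")
    g1, g2 = peaks.g1_peak, peaks.g2_peak
    g1_gate = (g1 * (1 - w_lo), g1)
    sg2 = (border[0] * g2, border[1] * g2)
    s_int = (g1 * (1 + w_hi), border[0] * g2)
    if not s_int[0] < s_int[1]:
        raise ConfigurationError("s_interval is empty: peaks too close or windows too wide")
    if singlet_rule is None:
        singlet_rule = (float("nan"), float("inf"))
    return GateSet(
        singlet_center=singlet_rule[0], singlet_cut=singlet_rule[1],
        g1_peak=g1, g2_peak=g2, g1_gate=g1_gate, s_interval=s_int, sg2_border=sg2,
        g2_inferred=peaks.g2_inferred, g1_ambiguous=peaks.g1_ambiguous,
    )


def _in_interval(x: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    return (x >= lo) & (x < hi)


def _in_g1_gate(x: np.ndarray, gates: GateSet) -> np.ndarray:
    # closed at the peak: the G1 gate is the left side of the peak *including*
    # the peak position itself (otherwise a zero-CV population, which sits
    # exactly at the peak, would gate empty); events right of the peak are out
    lo, hi = gates.g1_gate
    return (x >= lo) & (x <= hi)


def _robust_lognormal_quantile(x: np.ndarray, q: float) -> float:
    """Population ``q``-quantile under a log-normal model, estimated robustly.

    Location is the log-median and scale the normal-consistent MAD of the
    log signal, so a small bright contaminant tail cannot inflate the
    estimate the way an empirical extreme order statistic would. A constant
    sample returns that constant for any q.
    """
    from scipy.stats import norm

    lx = np.log10(np.maximum(x, _LOG_FLOOR))
    med = float(np.median(lx))
    mad = float(np.median(np.abs(lx - med))) * 1.4826
    return float(10.0 ** (med + norm.ppf(q) * mad))


def derive_mcm_threshold(events: pd.DataFrame, gates: GateSet, q: float = 0.99,
                         estimator: str = "lognormal") -> float:
    """MCM-positivity threshold from cells at the S/G2 border.

    At the S/G2 border MCM offloading is complete, so border events carry
    only background MCM signal; the threshold is their ``q``-quantile
    ("exceeding the signal obtained from cells at the S/G2 border"),
    estimated robustly under a log-normal model by default
    (``estimator="empirical"`` uses the raw order statistic).
    """
    if not 0 < q < 1:
        raise ConfigurationError("quantile q must be in (0, 1)")
    if estimator not in ("lognormal", "empirical"):
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    _require_measurement_columns(events, ["dna_area", "mcm_signal"])
    border = events.loc[_in_interval(events["dna_area"].to_numpy(), gates.sg2_border)]
    if len(border) < 30:
        raise AnalysisError(
            f"only {len(border)} events in the S/G2 border window; "
            "too few for a population threshold — consider the secondary-antibody "
            "control mode (derive_threshold_from_control)")
    x = border["mcm_signal"].to_numpy()
    if estimator == "lognormal":
        thr = _robust_lognormal_quantile(x, q)
        if not np.all(x > 0):  # degenerate zero-signal data: fall back to exact
            thr = float(np.quantile(x, q))
    else:
        thr = float(np.quantile(x, q))
    log.info("mcm_threshold=%.4g from %d S/G2-border events (q=%.3g)", thr, len(border), q)
    return thr


def derive_mcm_threshold_bimodal(events: pd.DataFrame, gates: GateSet,
                                 min_separation: float = 0.5) -> float:
    """MCM threshold as the geometric midpoint of the G1 bimodality.

    Fallback for samples with no populated S/G2-border window (for example a
    release experiment harvested before any cell reaches late S): the gated
    G1 population splits into an unloaded (background) and a loaded mode on
    the log scale, and the threshold is placed between them — the same
    negative-reference logic the secondary-antibody control provides.
    Requires the two modes to be at least ``min_separation`` decades apart.
    """
    _require_measurement_columns(events, ["dna_area", "mcm_signal"])
    g1 = events.loc[_in_g1_gate(events["dna_area"].to_numpy(), gates), "mcm_signal"].to_numpy()
    if len(g1) < 30:
        raise AnalysisError(f"only {len(g1)} events in the G1 gate")
    modes = _log_modes(g1)
    if len(modes) < 2 or modes[-1] - modes[0] < min_separation:
        raise AnalysisError(
            "G1 MCM distribution is unimodal; cannot place a bimodal threshold — "
            "use the S/G2-border or secondary-antibody control mode")
    thr = float(10.0 ** (0.5 * (modes[0] + modes[-1])))
    log.info("mcm_threshold=%.4g from G1 bimodality (modes 10^%.3f, 10^%.3f)",
             thr, modes[0], modes[-1])
    return thr


def _log_density(lx: np.ndarray, bins: int = 256, smooth: float = 3.0):
    lo, hi = lx.min(), lx.max()
    if hi - lo < 1e-9:
        return None, None
    counts, edges = np.histogram(lx, bins=bins, range=(lo, hi))
    sm = gaussian_filter1d(counts.astype(float), smooth)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, sm


def _log_modes(x: np.ndarray, min_height: float = 0.05):
    """Mode locations (log10 units) of a positive signal, largest last."""
    lx = np.log10(np.maximum(x, _LOG_FLOOR))
    centers, sm = _log_density(lx)
    if centers is None:  # (near-)constant signal
        return [float(np.median(lx))]
    idx, _ = find_peaks(sm, prominence=min_height * sm.max(), height=min_height * sm.max())
    if len(idx) == 0:
        idx = [int(np.argmax(sm))]
    return sorted(float(centers[i]) for i in idx)


def derive_rb1_threshold(events: pd.DataFrame, gates: GateSet,
                         q_rb: float = 0.995, min_separation: float = 0.3,
                         min_fraction: float = 0.005) -> tuple[float, bool]:
    """RB1-positivity threshold between anchored G1 cells and S-phase cells.

    S-phase cells are the built-in negative reference: their RB1 is
    hyper-phosphorylated and washed out by the extraction. The threshold is
    the geometric midpoint between the mode of the S-phase log signal and the
    upper mode of the G1 log signal. When G1 is unimodal (no anchored
    population, or it coincides with the reference within ``min_separation``
    decades) the fallback is the ``q_rb``-quantile of the S-phase
    distribution; the returned flag is then True.
    """
    _require_measurement_columns(events, ["dna_area", "rb1_signal"])
    dna = events["dna_area"].to_numpy()
    s_ev = events.loc[_in_interval(dna, gates.s_interval), "rb1_signal"].to_numpy()
    g1_ev = events.loc[_in_g1_gate(dna, gates), "rb1_signal"].to_numpy()
    # a real S population, not just the DNA-noise tail of the G1 peak:
    # require both an absolute count and a minimum share of all events
    if len(s_ev) < 30 or len(s_ev) < min_fraction * len(events):
        raise AnalysisError(
            f"only {len(s_ev)}/{len(events)} events in the S interval; no S-phase "
            "negative reference — consider the secondary-antibody control mode "
            "(derive_threshold_from_control) or derive_rb1_threshold_g1_only")
    if len(g1_ev) < 30:
        raise AnalysisError(f"only {len(g1_ev)} events in the G1 gate")
    s_mode = _log_modes(s_ev)[0]
    g1_upper = _log_modes(g1_ev)[-1]
    if g1_upper - s_mode < min_separation:
        thr = float(np.quantile(s_ev, q_rb))
        log.info("rb1 threshold fallback (G1 unimodal): q%.3f of S-phase = %.4g", q_rb, thr)
        return thr, True
    thr = float(10.0 ** (0.5 * (s_mode + g1_upper)))
    log.info("rb1_threshold=%.4g (S mode 10^%.3f, G1 upper mode 10^%.3f)", thr, s_mode, g1_upper)
    return thr, False


def derive_rb1_threshold_g1_only(events: pd.DataFrame, gates: GateSet,
                                 min_separation: float = 0.3,
                                 offset_decades: float = 1.5) -> tuple[float, bool]:
    """RB1 threshold for samples with no S-phase negative reference.

    An arrested population (for example an irradiated release, blocked
    before the restriction point) never produces the S-phase cells whose
    washed-out RB1 anchors :func:`derive_rb1_threshold`. If the G1 log
    distribution is bimodal the threshold is the geometric midpoint of its
    extreme modes; if unimodal, it is placed ``offset_decades`` below the
    single mode, treating the whole G1 population as RB1-positive — a
    sample with *no* anchored cells is indistinguishable from this blindly,
    so the second return value flags the assumption. Prefer thresholds from
    a pooled/barcoded control when one exists.
    """
    _require_measurement_columns(events, ["dna_area", "rb1_signal"])
    g1 = events.loc[_in_g1_gate(events["dna_area"].to_numpy(), gates), "rb1_signal"].to_numpy()
    if len(g1) < 30:
        raise AnalysisError(f"only {len(g1)} events in the G1 gate")
    modes = _log_modes(g1)
    if len(modes) >= 2 and modes[-1] - modes[0] >= min_separation:
        return float(10.0 ** (0.5 * (modes[0] + modes[-1]))), False
    thr = float(10.0 ** (modes[-1] - offset_decades))
    log.warning("no RB1 negative reference and unimodal G1; threshold %.4g placed "
                "%.1f decades below the G1 mode (all G1 treated RB1-positive)",
                thr, offset_decades)
    return thr, True


def derive_threshold_from_control(control_events: pd.DataFrame, channel: str,
                                  q: float = 0.995) -> float:
    """Positivity threshold from a secondary-antibody-only control sample."""
    if not 0 < q < 1:
        raise ConfigurationError("quantile q must be in (0, 1)")
    if len(control_events) < 100:
        raise InputError(f"need >= 100 control events, got {len(control_events)}")
    _require_measurement_columns(control_events, [channel])
    return float(np.quantile(control_events[channel].to_numpy(), q))


def classify_quadrants(events: pd.DataFrame, gates: GateSet, label: str = "") -> QuadrantResult:
    """Assign each G1-gated event to one quadrant by strict thresholding.

    Positivity is strict (signal > threshold; ties are negative). Q1 is
    MCM+/RB1-, Q2 MCM+/RB1+, Q3 MCM-/RB1+, Q4 MCM-/RB1-. Q2 and Q3 are
    before the restriction point (anchored RB1); Q1 after; Q4 is ambiguous
    (either post-restriction-point and not yet loaded, or very early G1 with
    RB1 not yet phosphorylated).
    """
    if gates.mcm_threshold is None or gates.rb1_threshold is None:
        raise ConfigurationError("GateSet thresholds not derived yet")
    _require_measurement_columns(events, ["dna_area", "mcm_signal", "rb1_signal"])
    g1 = events.loc[_in_g1_gate(events["dna_area"].to_numpy(), gates)]
    n = len(g1)
    if n == 0:
        raise AnalysisError("zero events in the G1 gate")
    mcm_pos = g1["mcm_signal"].to_numpy() > gates.mcm_threshold
    rb1_pos = g1["rb1_signal"].to_numpy() > gates.rb1_threshold
    n1 = int(np.sum(mcm_pos & ~rb1_pos))
    n2 = int(np.sum(mcm_pos & rb1_pos))
    n3 = int(np.sum(~mcm_pos & rb1_pos))
    n4 = int(np.sum(~mcm_pos & ~rb1_pos))
    assert n1 + n2 + n3 + n4 == n
    return QuadrantResult(
        n_q1=n1, n_q2=n2, n_q3=n3, n_q4=n4, n_total=n,
        frac_q1=n1 / n, frac_q2=n2 / n, frac_q3=n3 / n, frac_q4=n4 / n,
        ci_q1=wilson_ci(n1, n), ci_q2=wilson_ci(n2, n),
        ci_q3=wilson_ci(n3, n), ci_q4=wilson_ci(n4, n),
        gate_provenance=gates.to_dict(), label=label,
    )


def fraction_s_phase(events: pd.DataFrame, gates: GateSet) -> SPhaseFraction:
    """Fraction of (singlet) events with DNA content in the S interval."""
    _require_measurement_columns(events, ["dna_area"])
    n = len(events)
    if n == 0:
        raise InputError("empty events table")
    k = int(_in_interval(events["dna_area"].to_numpy(), gates.s_interval).sum())
    return SPhaseFraction(fraction=k / n, ci=wilson_ci(k, n), n=n)


def auto_gate(events: pd.DataFrame, *, k_mad: float = 4.0, w_lo: float = 0.10,
              w_hi: float = 0.10, border: tuple[float, float] = (0.90, 0.98),
              mcm_quantile: float = 0.99, rb1_q_fallback: float = 0.995):
    """Run the whole gating chain and return (singlet events, GateSet)."""
    singlets, rule = gate_singlets(events, k_mad=k_mad)
    peaks = find_dna_peaks(singlets)
    gates = define_gates(singlets, peaks, singlet_rule=rule,
                         w_lo=w_lo, w_hi=w_hi, border=border)
    gates.mcm_threshold = derive_mcm_threshold(singlets, gates, q=mcm_quantile)
    thr, fallback = derive_rb1_threshold(singlets, gates, q_rb=rb1_q_fallback)
    gates.rb1_threshold = thr
    gates.rb1_fallback = fallback
    return singlets, gates
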