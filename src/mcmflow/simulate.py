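"""Ground-truthed synthetic cytometry populations.

This module generates single cells with a known cell-cycle state under four
experimental scenarios, and turns them into noisy list-mode cytometry events:

* ``exponential`` — asynchronous exponential growth with the standard
  age density p(a) = (2 ln2 / T) 2^(-a/T) on [0, T];
* ``g0_release`` — quiescent fibroblasts released into the cycle
  (restriction-point passage from ~9 h, MCM loading from ~11 h, S entry from
  ~14.5 h under the BJ defaults);
* ``irradiated_g0_release`` — the same release but with the restriction point
  blocked by irradiation (no cell ever hyper-phosphorylates RB1) and MCM
  loading delayed;
* ``nocodazole_release`` — synchronized mitotic exit with two waves of MCM
  loading: a fast, post-restriction-point wave and a slow wave that loads
  while RB1 is still anchored.

The biological model: RB1 is unphosphorylated (and unanchored) immediately
after G0 exit or mitosis, becomes mono/hypo-phosphorylated and anchored at
``t_hypo``, and is hyper-phosphorylated (released — the restriction point) at
the cell's ``t_rp``. Chromatin-bound MCM ramps linearly from 0 to 1 over
``load_duration`` after the cell's loading onset, and is offloaded during S
phase, completing by ``s_offload_end`` of S (forks terminating).

Only chromatin-bound MCM and anchored (hypo-phosphorylated) RB1 survive the
pre-fixation salt/detergent extraction, so the measured RB1 signal reports
the anchored state and the measured MCM signal reports loaded fraction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

PHASES = ("G0", "G1", "S", "G2M")
RB1_STATES = ("unphosphorylated", "hypo_phosphorylated", "hyper_phosphorylated")

#: columns produced by :func:`apply_measurement_model` (instrument channels)
MEASUREMENT_COLUMNS = ("dna_area", "dna_width", "mcm_signal", "rb1_signal", "barcode_signal")
#: ground-truth columns carried alongside the measurements
TRUTH_COLUMNS = (
    "cell_id", "phase", "s_fraction", "rb1_state", "rp_passed",
    "mcm_loaded_fraction", "dna_content", "sample_id", "is_doublet",
)

_KINDS = ("exponential", "g0_release", "nocodazole_release", "irradiated_g0_release")
_SYNCHRONIZED = ("g0_release", "nocodazole_release", "irradiated_g0_release")


@dataclass
class ScenarioConfig:
    """Biological scenario: cell-cycle structure and event timing.

    All times are hours. ``t_rp_mean``/``t_load_mean`` are population onsets
    measured from the scenario origin (G0 release or mitotic exit for the
    synchronized kinds; cell birth for ``exponential``); per-cell jitter is
    half-normal (Gaussian truncated at 0) so the population onset is the
    configured mean. ``frac_pre_rp_loaders`` is the fraction of cells whose
    MCM-loading onset precedes their restriction-point passage — the quantity
    quadrant Q2 measures.
    """

    kind: str = "exponential"
    T_G1: float = 10.0
    T_S: float = 8.0
    T_G2M: float = 4.0
    t_rp_mean: float = 6.0
    t_rp_sd: float = 1.0
    t_load_mean: float = 8.0
    t_load_sd: float = 1.0
    load_duration: float = 3.0
    frac_pre_rp_loaders: float = 0.0
    t_hypo: float = 0.5
    t_hypo_sd: float = 0.25
    t_s_sd: float = 1.5
    s_offload_end: float = 0.70
    timepoints: tuple[float, ...] = (0.0,)
    n_cells: int = 10_000
    seed: int = 0
    rp_blocked: bool = False
    irr_load_delay: float = 10.0
    g2m_loaded_frac: float = 0.0
    # nocodazole two-wave parameters (fast wave uses t_rp_mean / t_load_mean)
    noc_fast_fraction: float = 0.5
    t_rp_slow_mean: float = 13.0
    t_rp_slow_sd: float = 2.0
    t_load_slow_mean: float = 6.0
    t_load_slow_sd: float = 2.0
    sample_id: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown scenario kind {self.kind!r}; expected one of {_KINDS}")
        for name in ("T_G1", "T_S", "T_G2M", "load_duration"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {getattr(self, name)}")
        for name in ("t_rp_sd", "t_load_sd", "t_hypo_sd", "t_s_sd", "t_rp_slow_sd", "t_load_slow_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("frac_pre_rp_loaders", "noc_fast_fraction", "g2m_loaded_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.s_offload_end <= 1.0:
            raise ConfigurationError("s_offload_end must be in (0, 1]")
        tp = tuple(float(t) for t in self.timepoints)
        if any(t < 0 for t in tp):
            raise ConfigurationError("timepoints must be >= 0")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigurationError("timepoints must be strictly increasing")
        object.__setattr__(self, "timepoints", tp)
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        if self.kind == "irradiated_g0_release":
            object.__setattr__(self, "rp_blocked", True)

    @property
    def cycle_length(self) -> float:
        return self.T_G1 + self.T_S + self.T_G2M

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class OpticsConfig:
    """Instrument model: gains, backgrounds, noise and artefacts.

    Noise is multiplicative log-normal per channel, parameterized by its
    coefficient of variation (mean-1 normalization, so the sample CV of a
    constant signal equals ``cv``). Backgrounds (autofluorescence plus
    nonspecific secondary antibody) are log-normal around the stated mean with
    the same channel CV. ``barcode_levels`` defaults to a 4-fold dilution
    series mirroring a 4-level Pacific Blue barcoding stain.
    """

    gain_dna: float = 100.0
    gain_mcm: float = 1000.0
    gain_rb1: float = 1000.0
    background_dna: float = 0.0
    background_mcm: float = 10.0
    background_rb1: float = 10.0
    cv_dna: float = 0.03
    cv_width: float = 0.05
    cv_mcm: float = 0.25
    cv_rb1: float = 0.25
    base_width: float = 100.0
    doublet_rate: float = 0.0
    doublet_width_factor: float = 1.6
    barcode_levels: tuple[float, ...] = (1000.0, 250.0, 62.5, 15.625)
    barcode_cv: float = 0.15

    def __post_init__(self) -> None:
        for name in ("gain_dna", "gain_mcm", "gain_rb1", "base_width"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("background_dna", "background_mcm", "background_rb1",
                     "cv_dna", "cv_width", "cv_mcm", "cv_rb1", "barcode_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ConfigurationError("doublet_rate must be in [0, 1]")
        if not self.doublet_width_factor > 1.0:
            raise ConfigurationError("doublet_width_factor must be > 1")
        levels = tuple(float(x) for x in self.barcode_levels)
        if len(set(levels)) != len(levels):
            raise ConfigurationError("barcode_levels must be pairwise distinct")
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ConfigurationError("barcode_levels must be strictly decreasing")
        object.__setattr__(self, "barcode_levels", levels)

    def replace(self, **kw) -> "OpticsConfig":
        return dataclasses.replace(self, **kw)


#: Named scenario presets.  Cycle-phase durations and onset times follow the
#: study conditions for each cell system: BJ fibroblasts released from
#: contact-inhibition G0 pass the restriction point from ~9 h, start loading
#: MCM from ~11 h and enter S from ~14.5-15 h; irradiation (6 Gy at 1 h after
#: release) blocks restriction-point passage and delays loading; U2OS cells
#: released from a nocodazole mitotic block enter S by ~10 h with a fast
#: post-restriction-point loading wave (1.5-4 h) and a slow anchored-RB1 wave
#: (6-8 h).
SCENARIO_PRESETS: dict[str, dict] = {
    "bj_exponential": dict(
        kind="exponential", T_G1=10.0, T_S=8.0, T_G2M=4.0,
        t_rp_mean=6.0, t_rp_sd=1.0, t_load_mean=8.0, t_load_sd=1.0,
        load_duration=3.0, frac_pre_rp_loaders=0.14, t_hypo=0.5, t_hypo_sd=0.25,
    ),
    "u2os_exponential": dict(
        kind="exponential", T_G1=5.0, T_S=8.0, T_G2M=4.0,
        t_rp_mean=2.0, t_rp_sd=0.6, t_load_mean=2.4, t_load_sd=0.6,
        load_duration=2.0, frac_pre_rp_loaders=0.11, t_hypo=0.3, t_hypo_sd=0.15,
    ),
    "bj_g0_release": dict(
        kind="g0_release", T_G1=14.5, T_S=8.0, T_G2M=4.0,
        t_rp_mean=9.0, t_rp_sd=1.5, t_load_mean=11.0, t_load_sd=1.5,
        load_duration=3.0, frac_pre_rp_loaders=0.0, t_hypo=2.0, t_hypo_sd=0.75,
        t_s_sd=1.5, timepoints=(0.0, 3.0, 6.0, 9.0, 11.0, 13.0, 15.0, 20.0),
    ),
    "bj_irradiated_g0_release": dict(
        kind="irradiated_g0_release", T_G1=14.5, T_S=8.0, T_G2M=4.0,
        t_rp_mean=9.0, t_rp_sd=1.5, t_load_mean=11.0, t_load_sd=1.5,
        load_duration=3.0, frac_pre_rp_loaders=0.0, t_hypo=2.0, t_hypo_sd=0.75,
        t_s_sd=1.5, rp_blocked=True, irr_load_delay=10.0,
        timepoints=(10.0, 13.0, 16.0, 20.0, 24.0),
    ),
    "u2os_nocodazole_release": dict(
        kind="nocodazole_release", T_G1=10.0, T_S=8.0, T_G2M=4.0,
        t_rp_mean=0.8, t_rp_sd=0.3, t_load_mean=1.5, t_load_sd=1.0,
        load_duration=2.0, t_hypo=0.5, t_hypo_sd=0.25, t_s_sd=2.5,
        noc_fast_fraction=0.5, t_rp_slow_mean=13.0, t_rp_slow_sd=2.0,
        t_load_slow_mean=6.0, t_load_slow_sd=2.0,
        timepoints=(0.0, 1.5, 3.0, 4.5, 6.0, 8.0, 10.0, 12.0),
    ),
}


def get_scenario(name: str, **overrides) -> ScenarioConfig:
    """Look up a named scenario preset, optionally overriding fields."""
    try:
        base = SCENARIO_PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario preset {name!r}; available: {sorted(SCENARIO_PRESETS)}"
        ) from None
    return ScenarioConfig(**{**base, **overrides})


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(s) & 0x7FFFFFFF for s in streams]])


def _half_normal(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    """One-sided jitter: |N(0, sd)| (a Gaussian truncated at 0)."""
    if sd == 0:
        return np.zeros(n)
    return np.abs(rng.normal(0.0, sd, n))


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": pd.Series(dtype=np.int64),
        "phase": pd.Series(dtype=object),
        "s_fraction": pd.Series(dtype=float),
        "rb1_state": pd.Series(dtype=object),
        "rp_passed": pd.Series(dtype=bool),
        "mcm_loaded_fraction": pd.Series(dtype=float),
        "dna_content": pd.Series(dtype=float),
        "sample_id": pd.Series(dtype=np.int64),
    })


def simulate_cells(scenario: ScenarioConfig, timepoint: float) -> pd.DataFrame:
    """Draw ``scenario.n_cells`` ground-truth cells observed at ``timepoint``.

    Returns a DataFrame of CellState records (one row per cell). For the
    synchronized kinds the timepoint must be one of ``scenario.timepoints``
    (the sampling design); the asynchronous ``exponential`` kind is
    timepoint-free and accepts any value.
    """
    if scenario.kind in _SYNCHRONIZED:
        if not any(abs(timepoint - t) < 1e-9 for t in scenario.timepoints):
            raise ConfigurationError(
                f"timepoint {timepoint} not in scenario.timepoints {scenario.timepoints}"
            )
    n = scenario.n_cells
    if n == 0:
        return _empty_cells()
    rng = _rng(scenario.seed, round(float(timepoint) * 1000), 11)
    if scenario.kind == "exponential":
        df = _simulate_exponential(scenario, rng)
    elif scenario.kind in ("g0_release", "irradiated_g0_release"):
        df = _simulate_g0_release(scenario, float(timepoint), rng)
    else:
        df = _simulate_nocodazole(scenario, float(timepoint), rng)
    df["cell_id"] = np.arange(n, dtype=np.int64)
    df["sample_id"] = np.full(n, scenario.sample_id, dtype=np.int64)
    cols = ["cell_id", "phase", "s_fraction", "rb1_state", "rp_passed",
            "mcm_loaded_fraction", "dna_content", "sample_id"]
    return df[cols]


def _assemble(phase, s_fraction, rb1_state, rp_passed, mcm, dna) -> pd.DataFrame:
    return pd.DataFrame({
        "phase": phase,
        "s_fraction": s_fraction,
        "rb1_state": rb1_state,
        "rp_passed": rp_passed,
        "mcm_loaded_fraction": mcm,
        "dna_content": dna,
    })


def _states_from_clock(scenario: ScenarioConfig, t_obs: np.ndarray,
                       t_hypo: np.ndarray, t_rp: np.ndarray,
                       t_load: np.ndarray, t_s: np.ndarray,
                       pre_g1_phase: str) -> pd.DataFrame:
    """Map per-cell event times and an observation clock onto cell states.

    ``t_obs`` is each cell's time on its own cycle clock. Cells with
    ``t_obs < t_hypo`` are in the pre-anchoring state (``pre_g1_phase`` with
    unphosphorylated RB1); anchored G1 until ``t_rp``; hyper-phosphorylated
    thereafter; S from ``t_s`` for ``T_S`` hours; G2M beyond.
    """
    n = len(t_obs)
    phase = np.full(n, "G1", dtype=object)
    rb1 = np.full(n, "hypo_phosphorylated", dtype=object)
    s_frac = np.zeros(n)
    dna = np.full(n, 2.0)
    mcm = np.clip((t_obs - t_load) / scenario.load_duration, 0.0, 1.0)

    pre = t_obs < t_hypo
    phase[pre] = pre_g1_phase
    rb1[pre] = "unphosphorylated"

    rp_passed = t_obs >= t_rp
    rb1[rp_passed] = "hyper_phosphorylated"

    in_s = t_obs >= t_s
    s = np.clip((t_obs[in_s] - t_s[in_s]) / scenario.T_S, 0.0, None)
    done = s >= 1.0
    s_frac[in_s] = np.where(done, 0.0, s)
    # loading is complete at S entry by construction (t_s >= t_load + load_duration)
    mcm[in_s] = np.maximum(0.0, 1.0 - np.minimum(s, 1.0) / scenario.s_offload_end)
    dna[in_s] = np.where(done, 4.0, 2.0 * (1.0 + s))
    phase[in_s] = np.where(done, "G2M", "S")
    rb1[in_s] = "hyper_phosphorylated"
    rp_passed = rp_passed | in_s

    return _assemble(phase, s_frac, rb1, rp_passed, mcm, dna)


def _simulate_g0_release(scenario: ScenarioConfig, t: float, rng) -> pd.DataFrame:
    n = scenario.n_cells
    t_hypo = scenario.t_hypo + _half_normal(rng, scenario.t_hypo_sd, n)
    if scenario.rp_blocked:
        t_rp = np.full(n, np.inf)
        t_load = (scenario.t_load_mean + scenario.irr_load_delay
                  + _half_normal(rng, scenario.t_load_sd, n))
        t_load = np.maximum(t_load, t_hypo)
        t_s = np.full(n, np.inf)
    else:
        t_rp = scenario.t_rp_mean + _half_normal(rng, scenario.t_rp_sd, n)
        t_rp = np.maximum(t_rp, t_hypo)
        loader = rng.random(n) < scenario.frac_pre_rp_loaders
        t_load = np.maximum(t_rp, scenario.t_load_mean + _half_normal(rng, scenario.t_load_sd, n))
        t_load[loader] = (t_hypo[loader]
                          + rng.random(loader.sum()) * np.maximum(t_rp[loader] - t_hypo[loader], 0.0))
        t_s = scenario.T_G1 + _half_normal(rng, scenario.t_s_sd, n)
        t_s = np.maximum.reduce([t_s, t_load + scenario.load_duration, t_rp + 0.25])
    t_obs = np.full(n, t)
    return _states_from_clock(scenario, t_obs, t_hypo, t_rp, t_load, t_s, pre_g1_phase="G0")


def _simulate_exponential(scenario: ScenarioConfig, rng) -> pd.DataFrame:
    n = scenario.n_cells
    T = scenario.cycle_length
    u = rng.random(n)
    age = -T * np.log2(1.0 - u / 2.0)  # exponential-growth age density

    t_hypo = scenario.t_hypo + _half_normal(rng, scenario.t_hypo_sd, n)
    t_hypo = np.minimum(t_hypo, scenario.T_G1)  # anchoring happens within G1
    loader = rng.random(n) < scenario.frac_pre_rp_loaders
    # pre-restriction-point loaders: anchored and loading from birth (loading
    # can begin in late mitosis with RB1 still bound), hyper-phosphorylated
    # only at S entry — they occupy Q2 for their whole G1 transit, so the
    # snapshot Q2 occupancy recovers frac_pre_rp_loaders.
    t_rp = np.minimum(scenario.t_rp_mean + _half_normal(rng, scenario.t_rp_sd, n), scenario.T_G1)
    t_rp = np.maximum(t_rp, t_hypo)
    lag = max(scenario.t_load_mean - scenario.t_rp_mean, 0.0)
    t_load = t_rp + lag + _half_normal(rng, scenario.t_load_sd, n)
    t_hypo[loader] = 0.0
    t_rp[loader] = scenario.T_G1
    t_load[loader] = 0.0
    t_s = np.full(n, scenario.T_G1)

    df = _states_from_clock(scenario, age, t_hypo, t_rp, t_load, t_s, pre_g1_phase="G1")
    if scenario.g2m_loaded_frac > 0:
        g2m = (df["phase"] == "G2M").to_numpy()
        keep = g2m & (rng.random(n) < scenario.g2m_loaded_frac)
        df.loc[keep, "mcm_loaded_fraction"] = 1.0
        df.loc[keep, "rb1_state"] = "hypo_phosphorylated"
        df.loc[keep, "rp_passed"] = False
    return df


def _simulate_nocodazole(scenario: ScenarioConfig, t: float, rng) -> pd.DataFrame:
    n = scenario.n_cells
    t_exit = _half_normal(rng, 0.2, n)  # mitotic exit just after release
    fast = rng.random(n) < scenario.noc_fast_fraction

    t_hypo = np.empty(n)
    t_rp = np.empty(n)
    t_load = np.empty(n)
    # fast wave: immediate hyper-phosphorylation (never anchored), early loading
    nf = int(fast.sum())
    t_rp[fast] = scenario.t_rp_mean + _half_normal(rng, scenario.t_rp_sd, nf)
    t_hypo[fast] = t_rp[fast]  # unphosphorylated until hyper: no anchored window
    t_load[fast] = scenario.t_load_mean + _half_normal(rng, scenario.t_load_sd, nf)
    # slow wave: anchors early, loads at 6-8 h while still before the
    # restriction point, hyper-phosphorylates late
    ns = n - nf
    slow = ~fast
    t_hypo[slow] = scenario.t_hypo + _half_normal(rng, scenario.t_hypo_sd, ns)
    t_rp[slow] = scenario.t_rp_slow_mean + _half_normal(rng, scenario.t_rp_slow_sd, ns)
    t_load[slow] = scenario.t_load_slow_mean + _half_normal(rng, scenario.t_load_slow_sd, ns)

    t_s = np.empty(n)
    t_s[fast] = scenario.T_G1 + _half_normal(rng, scenario.t_s_sd, nf)
    t_s[slow] = np.maximum(t_rp[slow] + 1.5,
                           scenario.T_G1 + 4.0 + _half_normal(rng, scenario.t_s_sd, ns))
    t_s = np.maximum(t_s, t_load + scenario.load_duration)

    t_obs = np.full(n, t) - t_exit  # per-cell clock starts at mitotic exit
    df = _states_from_clock(scenario, t_obs, t_hypo, t_rp, t_load, t_s, pre_g1_phase="G1")
    # cells not yet out of mitosis are 4N G2M with previous-cycle hyper-RB1
    in_m = t_obs < 0
    df.loc[in_m, "phase"] = "G2M"
    df.loc[in_m, "dna_content"] = 4.0
    df.loc[in_m, "s_fraction"] = 0.0
    df.loc[in_m, "mcm_loaded_fraction"] = 0.0
    df.loc[in_m, "rb1_state"] = "hyper_phosphorylated"
    df.loc[in_m, "rp_passed"] = True
    return df


def _lognoise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative log-normal factor with mean 1 and CV ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, n))


def apply_measurement_model(cells: pd.DataFrame, optics: OpticsConfig, seed: int) -> pd.DataFrame:
    """Turn ground-truth cells into one noisy list-mode event each.

    Channel semantics: ``dna_area`` is proportional to DNA content (pulse
    area), ``dna_width`` is content-independent for single cells (pulse
    width), ``mcm_signal`` is proportional to the chromatin-bound MCM
    fraction, and ``rb1_signal`` carries a specific component only for cells
    with hypo-phosphorylated (anchored) RB1 — hyper-phosphorylated and
    unphosphorylated RB1 are washed out by the pre-fixation extraction.
    Deterministic for a fixed seed; ground-truth columns are carried through.
    """
    rng = _rng(seed, 23)
    n = len(cells)
    anchored = (cells["rb1_state"] == "hypo_phosphorylated").to_numpy() if n else np.zeros(0, bool)
    dna = cells["dna_content"].to_numpy() if n else np.zeros(0)
    mcm = cells["mcm_loaded_fraction"].to_numpy() if n else np.zeros(0)

    dna_area = optics.gain_dna * dna * _lognoise(rng, optics.cv_dna, n)
    if optics.background_dna > 0:
        dna_area = dna_area + optics.background_dna * _lognoise(rng, optics.cv_dna, n)
    dna_width = optics.base_width * _lognoise(rng, optics.cv_width, n)
    mcm_signal = optics.gain_mcm * mcm * _lognoise(rng, optics.cv_mcm, n)
    if optics.background_mcm > 0:
        mcm_signal = mcm_signal + optics.background_mcm * _lognoise(rng, optics.cv_mcm, n)
    rb1_signal = optics.gain_rb1 * anchored.astype(float) * _lognoise(rng, optics.cv_rb1, n)
    if optics.background_rb1 > 0:
        rb1_signal = rb1_signal + optics.background_rb1 * _lognoise(rng, optics.cv_rb1, n)

    out = pd.DataFrame({
        "dna_area": dna_area,
        "dna_width": dna_width,
        "mcm_signal": mcm_signal,
        "rb1_signal": rb1_signal,
    })
    for col in ("cell_id", "phase", "s_fraction", "rb1_state", "rp_passed",
                "mcm_loaded_fraction", "dna_content", "sample_id"):
        if col in cells.columns:
            out[col] = cells[col].to_numpy()
    out["is_doublet"] = np.zeros(n, dtype=bool)
    return out


def inject_doublets(events: pd.DataFrame, optics: OpticsConfig, seed: int) -> pd.DataFrame:
    """Append synthetic cell aggregates so that a fraction ``doublet_rate``
    of the output events are doublets.

    A doublet sums the fluorescence pulse areas of two randomly paired input
    events but is only ``doublet_width_factor`` times the mean of their pulse
    widths — the area-versus-width discrepancy that the singlet gate exploits.
    """
    rate = optics.doublet_rate
    if rate == 0:
        return events.copy()
    n = len(events)
    if n < 2:
        raise InputError("need at least 2 events to form doublets")
    rng = _rng(seed, 31)
    m = int(np.floor(n * rate / (1.0 - rate)))
    if m == 0:
        return events.copy()
    i = rng.integers(0, n, m)
    j = rng.integers(0, n, m)
    j = np.where(j == i, (j + 1) % n, j)  # never pair an event with itself
    a = events.iloc[i].reset_index(drop=True)
    b = events.iloc[j].reset_index(drop=True)
    dbl = a.copy()
    for col in ("dna_area", "mcm_signal", "rb1_signal", "barcode_signal"):
        if col in events.columns:
            dbl[col] = a[col].to_numpy() + b[col].to_numpy()
    dbl["dna_width"] = optics.doublet_width_factor * 0.5 * (
        a["dna_width"].to_numpy() + b["dna_width"].to_numpy())
    dbl["is_doublet"] = True
    out = pd.concat([events, dbl], ignore_index=True)
    return out


def barcode_and_pool(tables: list[pd.DataFrame], optics: OpticsConfig, seed: int) -> pd.DataFrame:
    """Stain each table with one barcode intensity level and pool them.

    Emulates fluorescent cell barcoding: each sample is stained with a
    distinct dye concentration (``optics.barcode_levels``, brightest first),
    all samples are mixed into one tube, and the pooled events are measured
    together. ``sample_id`` ground truth is preserved (or set to the table
    index when absent) and the pooled rows are shuffled.
    """
    levels = optics.barcode_levels
    if len(tables) != len(levels):
        raise ConfigurationError(
            f"{len(tables)} tables but {len(levels)} barcode levels")
    rng = _rng(seed, 41)
    stained = []
    for idx, (tbl, level) in enumerate(zip(tables, levels)):
        t = tbl.copy()
        t["barcode_signal"] = level * _lognoise(rng, optics.barcode_cv, len(t))
        if "sample_id" not in t.columns:
            t["sample_id"] = idx
        stained.append(t)
    pooled = pd.concat(stained, ignore_index=True)
    order = rng.permutation(len(pooled))
    return pooled.iloc[order].reset_index(drop=True)
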