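"""Synthetic MED64-style ventral-horn recordings with planted ground truth.

The simulator emulates a planar 8x8 multi-electrode array (75 um pitch,
20 kHz sampling) recording extracellularly from the ventral horn of a
neonatal spinal cord slice.  A condition preset (genotype x drug) fixes how
many electrodes carry supra-criterion spiking, how many distinct units each
of those electrodes records, and the aggregate firing rate per electrode;
the renderer plants refractory Poisson spike trains of distinct biphasic
waveform templates on those sites, on top of Gaussian noise and slow drift,
and returns the complete answer key (``GroundTruth``) alongside the voltage
matrix.  Every downstream stage (filtering, thresholding, sorting,
statistics) can therefore be scored against planted truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import tukey

DEFAULT_FS = 20_000.0
DEFAULT_DURATION = 50.0
SNIPPET_WINDOW = 64  # samples; shared with the detector's waveform window

GENOTYPES = ("control", "sma")
DRUGS = ("basal", "serotonin", "gaba", "acetylcholine", "bicuculline")


class SimulationError(ValueError):
    """Base class for simulator parameter errors."""


class InvalidTemplateError(SimulationError):
    pass


class InvalidParameterError(SimulationError):
    pass


class UnknownConditionError(KeyError):
    pass


class CapacityError(SimulationError):
    pass


@dataclass(frozen=True)
class ArrayGeometry:
    """Electrode grid geometry plus the subset of sites under tissue.

    The ventral horn covers only part of the probe; ``ventral_horn_mask``
    lists the flat electrode indices (row-major) considered to lie under
    the ventral horn.  Sites outside the mask record noise only.
    """

    n_rows: int = 8
    n_cols: int = 8
    spacing_um: float = 75.0
    ventral_horn_mask: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n_rows * self.n_cols != 64:
            raise SimulationError("expected a 64-electrode (8x8) grid")
        mask = tuple(sorted(set(self.ventral_horn_mask)))
        if not mask:
            raise SimulationError("ventral_horn_mask must be non-empty")
        if mask[0] < 0 or mask[-1] >= self.n_electrodes:
            raise SimulationError("mask indices out of range")
        object.__setattr__(self, "ventral_horn_mask", mask)

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def default(cls) -> "ArrayGeometry":
        # 6x6 corner sub-grid: the ventral horn covers just over half the
        # probe; 36 sites comfortably exceed every preset's demand.
        mask = tuple(r * 8 + c for r in range(6) for c in range(6))
        return cls(ventral_horn_mask=mask)


@dataclass(frozen=True)
class SpikeTemplate:
    """A fixed-window biphasic extracellular waveform in microvolts."""

    waveform: np.ndarray
    peak_amplitude_uv: float
    width_ms: float
    polarity: str  # "negative" | "positive"

    @property
    def extremum_index(self) -> int:
        return int(np.argmax(np.abs(self.waveform)))


@dataclass(frozen=True)
class UnitSpec:
    electrode: int
    template: SpikeTemplate
    rate_hz: float
    refractory_ms: float = 2.0
    jitter_sd: float = 0.03  # multiplicative amplitude jitter, fraction

    def __post_init__(self):
        if self.rate_hz < 0:
            raise InvalidParameterError("rate must be >= 0")
        if self.refractory_ms <= 0:
            raise InvalidParameterError("refractory must be > 0")
        if self.rate_hz * self.refractory_ms >= 1000.0:
            raise InvalidParameterError("rate x refractory leaves no room for a realizable train")


@dataclass(frozen=True)
class NoiseModel:
    """Stationary Gaussian noise plus slow drift (sinusoid + linear ramp).

    The drift lies below the 85 Hz high-pass cutoff so preprocessing must
    remove it; the ramp makes least-squares detrending consequential.
    """

    sd_uv: float = 5.0
    drift_amplitude_uv: float = 20.0
    drift_frequency_hz: float = 0.5

    def __post_init__(self):
        if self.sd_uv < 0:
            raise InvalidParameterError("noise sd must be >= 0")
        if self.drift_frequency_hz >= 85.0:
            raise InvalidParameterError("drift must stay below the 85 Hz high-pass cutoff")


@dataclass(frozen=True)
class ConditionPreset:
    """Planted activity levels for one genotype x drug condition."""

    genotype: str
    drug: str
    n_active_electrodes: int
    units_per_active_electrode: int
    aggregate_rate_hz: float
    inactive_rate_hz: float = 0.2

    def __post_init__(self):
        if self.aggregate_rate_hz < 1.0:
            raise InvalidParameterError("active sites must fire at >= 1 Hz aggregate")
        if not 0 <= self.inactive_rate_hz < 1.0:
            raise InvalidParameterError("inactive background rate must be in [0, 1) Hz")


# (genotype, drug) -> (active electrodes/slice, units/active electrode,
# aggregate spike rate per active electrode in Hz).  Basal and serotonin
# values come from the reported means; the three pharmacology conditions use
# the summary-table rows, with units/electrode defaulting to the genotype's
# basal count (unreported for those drugs).
_PRESET_TABLE: dict[tuple[str, str], tuple[int, int, float]] = {
    ("control", "basal"): (15, 5, 6.08),
    ("sma", "basal"): (6, 4, 5.48),
    ("control", "serotonin"): (25, 7, 10.20),
    ("sma", "serotonin"): (11, 5, 6.98),
    ("control", "acetylcholine"): (14, 5, 5.88),
    ("sma", "acetylcholine"): (6, 4, 5.39),
    ("control", "bicuculline"): (16, 5, 5.96),
    ("sma", "bicuculline"): (7, 4, 6.18),
    ("control", "gaba"): (14, 5, 5.74),
    ("sma", "gaba"): (6, 4, 5.14),
}


def build_preset(genotype: str, drug: str) -> ConditionPreset:
    """Look up the planted-activity preset for a genotype x drug pair."""
    key = (str(genotype).lower(), str(drug).lower())
    if key not in _PRESET_TABLE:
        raise UnknownConditionError(f"unknown condition {genotype!r} x {drug!r}")
    n_active, n_units, rate = _PRESET_TABLE[key]
    return ConditionPreset(
        genotype=key[0],
        drug=key[1],
        n_active_electrodes=n_active,
        units_per_active_electrode=n_units,
        aggregate_rate_hz=rate,
    )


@dataclass
class GroundTruth:
    """The simulator's answer key: everything planted, per (electrode, unit)."""

    spike_times: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    templates: dict[tuple[int, int], SpikeTemplate] = field(default_factory=dict)
    rates: dict[tuple[int, int], float] = field(default_factory=dict)
    active: np.ndarray = field(default_factory=lambda: np.zeros(64, dtype=bool))

    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.spike_times.values()))

    def counts_per_electrode(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for (e, _u), t in self.spike_times.items():
            counts[e] = counts.get(e, 0) + len(t)
        return counts

    def electrode_spike_times(self, electrode: int) -> np.ndarray:
        """All planted spike times on one electrode, pooled and sorted."""
        pooled = [t for (e, _u), t in self.spike_times.items() if e == electrode]
        if not pooled:
            return np.empty(0)
        return np.sort(np.concatenate(pooled))


@dataclass
class RecordingSegment:
    """One 50-s multi-channel voltage segment in microvolts.

    ``samples`` is (n_electrodes, n_samples) float32; row index is the flat
    electrode index of the geometry.
    """

    samples: np.ndarray
    fs: float
    duration: float
    geometry: ArrayGeometry
    genotype: str = ""
    drug: str = ""
    slice_id: str = ""
    segment_id: str = ""

    def __post_init__(self):
        n = int(round(self.fs * self.duration))
        if self.samples.shape != (self.geometry.n_electrodes, n):
            raise SimulationError(
                f"samples shape {self.samples.shape} does not match "
                f"({self.geometry.n_electrodes}, {n})"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def condition(self) -> str:
        return f"{self.genotype}:{self.drug}"


def make_template(
    peak_amplitude_uv: float,
    width_ms: float,
    polarity: str = "negative",
    window: int = SNIPPET_WINDOW,
    fs: float = DEFAULT_FS,
    second_lobe: float = 0.55,
    lobe_side: str = "after",
) -> SpikeTemplate:
    """Build a biphasic spike waveform template.

    The shape is a main Gaussian lobe of FWHM ~ ``width_ms``/2 with a
    broader opposing lobe (relative amplitude ``second_lobe``) before or
    after it, tapered to zero at the window edges and scaled so the
    extremum equals exactly +/- ``peak_amplitude_uv``.
    """
    if peak_amplitude_uv <= 0:
        raise InvalidTemplateError("peak amplitude must be positive")
    if polarity not in ("negative", "positive"):
        raise InvalidTemplateError(f"unknown polarity {polarity!r}")
    if lobe_side not in ("after", "before"):
        raise InvalidTemplateError(f"unknown lobe side {lobe_side!r}")
    window_ms = window / fs * 1000.0
    if 1.8 * width_ms > 0.8 * window_ms:
        raise InvalidTemplateError(
            f"width {width_ms} ms too large for a {window}-sample window at {fs} Hz"
        )
    t = (np.arange(window) - window // 2) / fs * 1000.0  # ms, centered
    s1 = width_ms / 2.0 / 2.355  # main lobe FWHM = width/2
    s2 = 1.5 * s1
    d = 0.6 * width_ms if lobe_side == "after" else -0.6 * width_ms
    shape = np.exp(-(t**2) / (2 * s1**2)) - second_lobe * np.exp(-((t - d) ** 2) / (2 * s2**2))
    shape *= tukey(window, alpha=0.3)
    shape /= np.max(np.abs(shape))
    sign = -1.0 if polarity == "negative" else 1.0
    waveform = sign * peak_amplitude_uv * shape
    assert abs(waveform[0]) <= 0.01 * peak_amplitude_uv
    assert abs(waveform[-1]) <= 0.01 * peak_amplitude_uv
    return SpikeTemplate(
        waveform=waveform,
        peak_amplitude_uv=peak_amplitude_uv,
        width_ms=width_ms,
        polarity=polarity,
    )


def simulate_spike_train(
    rate_hz: float,
    duration_s: float,
    refractory_ms: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample a refractory (dead-time) Poisson spike train.

    Inter-spike intervals are ``refractory + Exponential(1/lam)`` with the
    exponential intensity ``lam`` inflated so the *realized* mean rate equals
    ``rate_hz`` exactly: mean ISI = refractory + (1 - rate*refractory)/rate
    = 1/rate.  Returns sorted times in seconds within [0, duration_s).
    """
    if rate_hz < 0:
        raise InvalidParameterError("rate must be >= 0")
    if rate_hz == 0 or duration_s <= 0:
        return np.empty(0)
    tau = refractory_ms / 1000.0
    if rate_hz * tau >= 1.0:
        raise InvalidParameterError("rate x refractory >= 1: train not realizable")
    rng = np.random.default_rng(rng)
    lam = rate_hz / (1.0 - rate_hz * tau)
    times: list[np.ndarray] = []
    t_last = 0.0
    # first interval drawn like every other (stationary renewal start)
    while t_last < duration_s:
        n_draw = max(16, int((duration_s - t_last) * rate_hz * 1.5) + 16)
        isis = tau + rng.exponential(1.0 / lam, size=n_draw)
        chunk = t_last + np.cumsum(isis)
        times.append(chunk)
        t_last = chunk[-1]
    all_times = np.concatenate(times)
    return all_times[all_times < duration_s]


def _unit_catalog(
    electrode: int,
    n_units: int,
    rates: np.ndarray,
    amp_scale: float,
    snr_range: tuple[float, float],
    refractory_ms: float,
    jitter_sd: float,
    window: int,
    fs: float,
) -> list[UnitSpec]:
    """Deterministic per-electrode unit catalog with discriminable templates.

    All units are negative-going (the dominant polarity of extracellular
    somatic spikes).  Each unit carries a binary code over three shape
    attributes — main-lobe width (0.4/1.0 ms), second-lobe depth
    (0.3/0.55; deeper lobes would rival the filtered main lobe and break
    peak alignment) and second-lobe side (after/before the peak) — chosen so
    attribute splits across a unit set are near-balanced: balanced splits
    make the corresponding wavelet coefficients strongly bimodal, which is
    what the deviation-from-normality feature selection keys on.  Peak
    amplitudes tile ``snr_range`` x noise SD, permuted so unit pairs whose
    codes differ in only one attribute sit on distant amplitude tiers.
    """
    codes = [(0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 0),
             (1, 1, 1), (0, 0, 1), (0, 1, 0), (1, 0, 0)]
    tier_perm = ([0], [0, 1], [0, 1, 2], [0, 1, 2, 3],
                 [1, 2, 3, 4, 0], [1, 2, 3, 4, 0, 5],
                 [1, 2, 3, 4, 0, 5, 6], [1, 2, 3, 4, 0, 5, 6, 7])
    if n_units > len(codes):
        raise InvalidParameterError(f"at most {len(codes)} units per electrode")
    tiers = np.linspace(snr_range[0], snr_range[1], n_units) * amp_scale
    units = []
    for i in range(n_units):
        w, depth, side = codes[i]
        tpl = make_template(
            peak_amplitude_uv=float(tiers[tier_perm[n_units - 1][i]]),
            width_ms=1.0 if w else 0.4,
            polarity="negative",
            window=window,
            fs=fs,
            second_lobe=0.55 if depth else 0.3,
            lobe_side="before" if side else "after",
        )
        units.append(
            UnitSpec(
                electrode=electrode,
                template=tpl,
                rate_hz=float(rates[i]),
                refractory_ms=refractory_ms,
                jitter_sd=jitter_sd,
            )
        )
    return units


def _plant_unit(
    trace: np.ndarray,
    unit: UnitSpec,
    times: np.ndarray,
    fs: float,
    rng: np.random.Generator,
) -> None:
    """Superpose the unit's template at each spike time (extremum-aligned)."""
    wf = unit.template.waveform
    peak = unit.template.extremum_index
    n = trace.shape[0]
    for t in times:
        scale = 1.0
        if unit.jitter_sd > 0:
            scale = max(0.25, 1.0 + rng.normal(0.0, unit.jitter_sd))
        start = int(round(t * fs)) - peak
        trace[start : start + len(wf)] += scale * wf
        assert start >= 0 and start + len(wf) <= n


def render_recording(
    geometry: ArrayGeometry,
    preset: ConditionPreset,
    noise: NoiseModel,
    seed: int,
    fs: float = DEFAULT_FS,
    duration: float = DEFAULT_DURATION,
    slice_id: str = "",
    segment_id: str = "seg0",
    units: list[UnitSpec] | None = None,
    refractory_ms: float = 2.0,
    jitter_sd: float = 0.03,
    snr_range: tuple[float, float] = (8.0, 15.0),
    window: int = SNIPPET_WINDOW,
) -> tuple[RecordingSegment, GroundTruth]:
    """Render one segment and its ground truth.

    When ``units`` is None (the normal path) active sites are drawn from the
    ventral-horn mask and populated from the preset: exactly
    ``units_per_active_electrode`` units whose rates sum to the preset's
    aggregate rate; the remaining in-mask sites carry a single
    sub-criterion background unit at ``inactive_rate_hz``.  Passing an
    explicit ``units`` list bypasses the preset placement (used for
    controlled fixtures).

    Deterministic: identical (arguments, seed) give bit-identical output.
    """
    n_samples = int(round(fs * duration))
    n_elec = geometry.n_electrodes
    ss = np.random.SeedSequence([int(seed), 0xA5])
    ss_sites, ss_trains, ss_noise, ss_jitter = ss.spawn(4)
    rng_sites = np.random.default_rng(ss_sites)

    truth = GroundTruth(active=np.zeros(n_elec, dtype=bool))
    margin = window / fs  # keep every template fully inside the segment
    train_span = duration - 2 * margin
    min_active_count = 1.0 * duration  # >=1 Hz activity criterion, scaled

    electrode_units: dict[int, list[UnitSpec]] = {}
    if units is not None:
        for u in units:
            electrode_units.setdefault(u.electrode, []).append(u)
        planted_active = sorted(electrode_units)
    else:
        mask = np.asarray(geometry.ventral_horn_mask)
        if preset.n_active_electrodes > len(mask):
            raise CapacityError(
                f"preset wants {preset.n_active_electrodes} active sites but the "
                f"ventral-horn mask has only {len(mask)}"
            )
        active_sites = np.sort(
            rng_sites.choice(mask, size=preset.n_active_electrodes, replace=False)
        )
        amp_scale = noise.sd_uv if noise.sd_uv > 0 else 1.0
        n_units = preset.units_per_active_electrode
        unit_rates = np.full(n_units, preset.aggregate_rate_hz / n_units)
        for e in active_sites:
            electrode_units[int(e)] = _unit_catalog(
                int(e), n_units, unit_rates, amp_scale, snr_range,
                refractory_ms, jitter_sd, window, fs,
            )
        if preset.inactive_rate_hz > 0:
            for e in mask:
                e = int(e)
                if e in electrode_units:
                    continue
                electrode_units[e] = _unit_catalog(
                    e, 1, np.array([preset.inactive_rate_hz]), amp_scale,
                    (snr_range[0], snr_range[0]), refractory_ms, jitter_sd,
                    window, fs,
                )
        planted_active = [int(e) for e in active_sites]

    # spike trains, redrawn (deterministically) if a train happens to land on
    # the wrong side of the activity criterion so planted truth is well-posed
    rng_trains = np.random.default_rng(ss_trains)
    train_times: dict[tuple[int, int], np.ndarray] = {}
    for e in sorted(electrode_units):
        wants_active = (units is None) and (e in planted_active)
        for attempt in range(100):
            cand = {}
            for k, u in enumerate(electrode_units[e]):
                t = simulate_spike_train(u.rate_hz, train_span, u.refractory_ms, rng_trains)
                cand[(e, k)] = t + margin
            if units is not None:
                break
            total = sum(len(t) for t in cand.values())
            if wants_active and total >= min_active_count:
                break
            if not wants_active and total < min_active_count:
                break
        train_times.update(cand)

    samples = np.zeros((n_elec, n_samples), dtype=np.float32)
    rng_jitter = np.random.default_rng(ss_jitter)
    t_axis = np.arange(n_samples, dtype=np.float64) / fs
    noise_streams = np.random.SeedSequence([int(seed), 0x17]).spawn(n_elec)
    for e in range(n_elec):
        rng_e = np.random.default_rng(noise_streams[e])
        trace = np.zeros(n_samples)
        if noise.sd_uv > 0:
            trace += rng_e.normal(0.0, noise.sd_uv, size=n_samples)
        if noise.drift_amplitude_uv > 0:
            phase = rng_e.uniform(0, 2 * np.pi)
            trace += noise.drift_amplitude_uv * np.sin(
                2 * np.pi * noise.drift_frequency_hz * t_axis + phase
            )
            trace += noise.drift_amplitude_uv * (2 * t_axis / duration - 1.0)
        for k, u in enumerate(electrode_units.get(e, [])):
            times = train_times.get((e, k), np.empty(0))
            _plant_unit(trace, u, times, fs, rng_jitter)
            truth.spike_times[(e, k)] = times
            truth.templates[(e, k)] = u.template
            truth.rates[(e, k)] = u.rate_hz
        samples[e] = trace.astype(np.float32)

    for e in planted_active:
        truth.active[e] = True

    if units is None and noise.sd_uv > 0:
        # detectability guarantee: every planted template clears 8x noise SD
        for tpl in truth.templates.values():
            assert tpl.peak_amplitude_uv / noise.sd_uv >= snr_range[0] - 1e-9

    segment = RecordingSegment(
        samples=samples,
        fs=fs,
        duration=duration,
        geometry=geometry,
        genotype=preset.genotype,
        drug=preset.drug,
        slice_id=slice_id,
        segment_id=segment_id,
    )
    return segment, truth
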