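"""Synthetic two-channel sleep-EEG cohorts with ground-truth asymmetries.

Each subject's recording holds one annotated normal-sleep and one annotated
obstructive-apnea (OSA) segment per channel.  Within a segment every band
carries an amplitude-scaled mixture of a band-center sinusoid and
band-limited noise,

    component = A * [(1-c) * sinusoid + c * band_noise] / SD(mixture),

where c is the complexity mix (0 = pure tone, minimal fuzzy entropy;
1 = band-limited noise, maximal).  The mixture is normalized to unit sample
variance before amplitude scaling, so the realized band energy is A^2 per
sample and the expected energy laterality has the closed form

    LI_E = (A_L^2 - A_R^2) / (A_L^2 + A_R^2).

Band noise is synthesized by FFT-masking white noise (exact band
confinement).  The generator emulates the amplitude hierarchy of sleep EEG
(delta strongest, theta weakest) and the complexity ordering
delta < theta < alpha < beta that falls out of band bandwidth; it does not
model sleep microstructure, apnea physiology, or artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import (
    BAND_EDGES_HZ,
    BAND_ORDER,
    CHANNELS,
    CONDITIONS,
    Annotation,
    Recording,
)

__all__ = [
    "BAND_CENTERS_HZ",
    "SynthSpec",
    "make_band_component",
    "synth_cohort",
    "make_eli_separation_scenario",
]

#: Sinusoid frequencies: midpoints of the printed band edges.
BAND_CENTERS_HZ: dict[str, float] = {
    "delta": 2.0,
    "theta": 5.5,
    "alpha": 10.5,
    "beta": 22.0,
}

#: Default per-band amplitudes (uV), mimicking the sleep-EEG strength
#: hierarchy: delta strongest, theta weakest, alpha/beta intermediate.
DEFAULT_BAND_AMPLITUDE_UV: dict[str, float] = {
    "delta": 40.0,
    "theta": 8.0,
    "alpha": 20.0,
    "beta": 15.0,
}

Key = tuple[str, str, str]  # (condition, band, channel)


def _full_table(value_by_band: dict[str, float] | float) -> dict[Key, float]:
    table = {}
    for cond in CONDITIONS:
        for band in BAND_ORDER:
            v = (
                value_by_band[band]
                if isinstance(value_by_band, dict)
                else float(value_by_band)
            )
            for ch in CHANNELS:
                table[(cond, band, ch)] = v
    return table


@dataclass
class SynthSpec:
    """Generative parameters for one cohort; identical seed => identical data.

    amplitude / complexity_mix are keyed by (condition, band, channel).
    amplitude_jitter_sd is the log-normal sigma of a per-(subject, band)
    factor applied identically to both channels and conditions, adding
    between-subject variability without perturbing any laterality ground
    truth.  broadband_noise_sd adds white noise (uV) across the whole
    recording.
    """

    n_subjects: int = 21
    fs: float = 200.0
    segment_s: float = 20.0
    amplitude: dict[Key, float] = field(
        default_factory=lambda: _full_table(DEFAULT_BAND_AMPLITUDE_UV)
    )
    complexity_mix: dict[Key, float] = field(default_factory=lambda: _full_table(1.0))
    broadband_noise_sd: float = 2.0
    amplitude_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("invalid spec: n_subjects must be >= 1")
        for key, amp in self.amplitude.items():
            if amp < 0:
                raise ValueError(f"invalid spec: negative amplitude at {key}")
        for key, mix in self.complexity_mix.items():
            if not 0.0 <= mix <= 1.0:
                raise ValueError(f"invalid spec: complexity_mix at {key} outside [0,1]")
        if self.broadband_noise_sd < 0 or self.amplitude_jitter_sd < 0:
            raise ValueError("invalid spec: negative noise level")

    def with_amplitude_ratio(
        self, band: str, ratio: float, condition: str | None = None, channel: str = "C3"
    ) -> "SynthSpec":
        """Copy with one channel's amplitude scaled by `ratio` in `band`
        (both conditions unless one is named)."""
        amp = dict(self.amplitude)
        conds = CONDITIONS if condition is None else (condition,)
        for cond in conds:
            amp[(cond, band, channel)] = amp[(cond, band, channel)] * ratio
        return replace(self, amplitude=amp)


def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise spectrally confined to [lo, hi] by FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0.0:
        raise ValueError("invalid band: no FFT bins inside the band")
    return x / sd


def make_band_component(
    band: str,
    amplitude: float,
    complexity_mix: float,
    fs: float,
    duration_s: float,
    rng: np.random.Generator,
    band_edges: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """One band-limited component: tone/noise mixture, unit variance, scaled.

    The random phase of the sinusoid and the noise realization are drawn
    from ``rng``; two calls with identically seeded generators are
    bit-identical.
    """
    edges = band_edges if band_edges is not None else BAND_EDGES_HZ
    if band not in edges or band not in BAND_CENTERS_HZ:
        raise ValueError(f"invalid band: {band!r}")
    lo, hi = edges[band]
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid band: edges ({lo}, {hi}) outside (0, {fs / 2})")
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    tone = np.sqrt(2.0) * np.sin(2.0 * np.pi * BAND_CENTERS_HZ[band] * t + phase)
    noise = _band_noise(n, fs, lo, hi, rng)
    mix = (1.0 - complexity_mix) * tone + complexity_mix * noise
    if amplitude == 0.0:
        return np.zeros(n)
    sd = mix.std()
    if sd == 0.0:
        return np.zeros(n)
    return amplitude * mix / sd


def _segment_signal(
    spec: SynthSpec,
    condition: str,
    channel: str,
    jitter: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    n = round(spec.segment_s * spec.fs)
    sig = np.zeros(n)
    for band in BAND_ORDER:
        amp = spec.amplitude[(condition, band, channel)] * jitter[band]
        mix = spec.complexity_mix[(condition, band, channel)]
        sig += make_band_component(band, amp, mix, spec.fs, spec.segment_s, rng)
    return sig


def synth_cohort(spec: SynthSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Generate the cohort and its analytic ground truth.

    Each recording is gap + normal segment + gap + OSA segment + gap, with
    annotations at the exact segment onsets.  The ground-truth table gives
    expected_li_e = (A_L^2 - A_R^2)/(A_L^2 + A_R^2) per (subject, band,
    condition); fuzzy-entropy laterality has no closed form and is only
    qualitatively ordered by the complexity mix.
    """
    rng = np.random.default_rng(spec.seed)
    gap_s = 2.0
    n_seg = round(spec.segment_s * spec.fs)
    n_gap = round(gap_s * spec.fs)
    n_total = 3 * n_gap + 2 * n_seg
    onsets = {"normal": gap_s, "OSA": 2 * gap_s + spec.segment_s}

    recordings: list[Recording] = []
    truth_rows = []
    for s in range(spec.n_subjects):
        subject = f"S{s + 1:02d}"
        jitter = {
            band: float(np.exp(rng.normal(0.0, spec.amplitude_jitter_sd)))
            for band in BAND_ORDER
        }
        chans = {}
        for ch in CHANNELS:
            x = rng.standard_normal(n_total) * spec.broadband_noise_sd
            for cond in CONDITIONS:
                start = round(onsets[cond] * spec.fs)
                x[start : start + n_seg] += _segment_signal(spec, cond, ch, jitter, rng)
            chans[ch] = x
        recordings.append(
            Recording(
                subject_id=subject,
                c3=chans["C3"],
                c4=chans["C4"],
                fs=spec.fs,
                annotations=[
                    Annotation(cond, onsets[cond], spec.segment_s) for cond in CONDITIONS
                ],
            )
        )
        for cond in CONDITIONS:
            for band in BAND_ORDER:
                a_l = spec.amplitude[(cond, band, "C3")]
                a_r = spec.amplitude[(cond, band, "C4")]
                denom = a_l**2 + a_r**2
                truth_rows.append(
                    {
                        "subject": subject,
                        "band": band,
                        "condition": cond,
                        "expected_li_e": (a_l**2 - a_r**2) / denom if denom > 0 else np.nan,
                        "mix_c3": spec.complexity_mix[(cond, band, "C3")],
                        "mix_c4": spec.complexity_mix[(cond, band, "C4")],
                    }
                )
    return recordings, pd.DataFrame(truth_rows)


def make_eli_separation_scenario(
    n_subjects: int = 21,
    seed: int = 0,
    effect: str = "both",
    strength_ratio: float = 1.3,
    complexity_drop: float = 1.0,
    complexity_bands: tuple[str, ...] = ("beta",),
) -> SynthSpec:
    """Cohort spec where OSA carries leftward asymmetry, normal is symmetric.

    effect="both" injects a left-dominant asymmetry into OSA segments in both
    strength (C3 amplitude * strength_ratio in every band) and complexity
    (C4 complexity mix lowered by complexity_drop in ``complexity_bands``,
    reducing right-hemisphere fuzzy entropy); "strength" / "complexity"
    inject only one; "none" is the null scenario.  Under "both", cohort-mean
    ELI(OSA) exceeds ELI(normal) for every lambda in [0, 1].

    The complexity asymmetry defaults to the beta band alone: fuzzy entropy
    at m=2 and 200 Hz responds strongly to the tone/noise mix only where the
    band is wide relative to the 1-s epoch (sleep complexity concentrates in
    beta anyway), and confining the spectral change to the topmost band keeps
    the slow bands' spectra identical across channels, so the strength
    laterality stays clean of cross-band leakage.
    """
    if effect not in ("both", "strength", "complexity", "none"):
        raise ValueError(f"invalid spec: effect {effect!r}")
    spec = SynthSpec(n_subjects=n_subjects, seed=seed)
    amp = dict(spec.amplitude)
    mix = dict(spec.complexity_mix)
    for band in BAND_ORDER:
        if effect in ("both", "strength"):
            amp[("OSA", band, "C3")] *= strength_ratio
        if effect in ("both", "complexity") and band in complexity_bands:
            mix[("OSA", band, "C4")] = max(0.0, mix[("OSA", band, "C4")] - complexity_drop)
    return replace(spec, amplitude=amp, complexity_mix=mix)
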