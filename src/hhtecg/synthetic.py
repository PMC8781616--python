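"""Synthetic data: Gaussian feature sets and waveform-level ECG fixtures.

Two generators make the whole pipeline testable without any external
database:

* :func:`simulate_features` draws 6-dimensional centroid feature vectors per
  rhythm class from independent per-feature normal distributions, emulating
  the construction of a balanced simulated training set from the per-class
  mean/sd of a small observed corpus.  :func:`reference_feature_model` supplies
  the published per-class (mu, sigma) table measured on annotated MIT-BIH-style
  records.

* :func:`simulate_ecg` builds template-based PQRST waveform trains with
  rhythm-specific modifications (premature beats, fibrillatory baseline,
  sustained wide-QRS runs).  These fixtures are openly synthetic: their
  contract is class separability through the featuring chain, not clinical
  realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .records import FEATURE_NAMES, SYMPTOM_IDS, SYMPTOM_NAMES, ECGRecord, FeatureRecord

logger = logging.getLogger(__name__)


@dataclass
class GaussianFeatureModel:
    """Per-class, per-feature independent normal model of the centroid features.

    ``params[symptom][feature_name] = (mu, sigma)`` for all five symptoms and
    all six features (frequencies in Hz, powers in MHS energy-per-second
    units).  No cross-feature covariance is modelled.
    """

    params: dict[int, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for symptom in SYMPTOM_IDS:
            if symptom not in self.params:
                raise ValueError(f"missing symptom {symptom} in feature model")
            for name in FEATURE_NAMES:
                if name not in self.params[symptom]:
                    raise ValueError(
                        f"missing (mu, sigma) for symptom {symptom}, feature {name}"
                    )
                mu, sigma = self.params[symptom][name]
                if sigma < 0:
                    raise ValueError("sigma must be non-negative")
                self.params[symptom][name] = (float(mu), float(sigma))

    def draw(
        self,
        symptom: int,
        feature: str,
        n: int,
        rng: np.random.Generator,
        truncate: bool = True,
    ) -> np.ndarray:
        """Draw ``n`` values of one feature for one symptom.

        With ``truncate=True`` negative draws are clipped to zero (frequencies
        and powers are physical quantities); disable for distribution-level
        checks of the raw normal moments.
        """
        mu, sigma = self.params[symptom][feature]
        values = rng.normal(mu, sigma, size=n)
        if truncate:
            n_neg = int(np.count_nonzero(values < 0))
            if n_neg:
                logger.debug(
                    "truncated %d/%d negative draws for symptom %d %s",
                    n_neg, n, symptom, feature,
                )
            values = np.clip(values, 0.0, None)
        return values


#: Published per-class (mu, sigma) of the six centroid features, measured on
#: 3-s frames of annotated MIT-BIH-style records (frequencies in Hz).
_REFERENCE_PARAMS: dict[int, dict[str, tuple[float, float]]] = {
    1: {  # NSR
        "f1_freq": (4.772, 0.787), "f1_pow": (1.167, 0.864),
        "f2_freq": (1.478, 0.527), "f2_pow": (1.344, 1.605),
        "f3_freq": (0.288, 0.261), "f3_pow": (0.645, 1.997),
    },
    2: {  # APC
        "f1_freq": (4.241, 0.798), "f1_pow": (0.791, 0.567),
        "f2_freq": (0.932, 0.504), "f2_pow": (1.223, 1.294),
        "f3_freq": (0.378, 0.257), "f3_pow": (1.461, 2.762),
    },
    3: {  # AFib
        "f1_freq": (3.571, 0.558), "f1_pow": (2.683, 1.214),
        "f2_freq": (1.049, 0.455), "f2_pow": (2.824, 2.053),
        "f3_freq": (0.327, 0.263), "f3_pow": (1.183, 2.024),
    },
    4: {  # VPC
        "f1_freq": (3.283, 0.973), "f1_pow": (3.196, 2.170),
        "f2_freq": (0.993, 0.503), "f2_pow": (4.548, 3.909),
        "f3_freq": (0.340, 0.264), "f3_pow": (1.449, 2.011),
    },
    5: {  # VT
        "f1_freq": (3.120, 1.123), "f1_pow": (6.504, 6.250),
        "f2_freq": (1.013, 0.489), "f2_pow": (6.923, 7.274),
        "f3_freq": (0.315, 0.265), "f3_pow": (1.184, 1.070),
    },
}


def reference_feature_model() -> GaussianFeatureModel:
    """The published 30-cell (mu, sigma) feature table as a Gaussian model."""
    return GaussianFeatureModel(
        params={s: dict(cells) for s, cells in _REFERENCE_PARAMS.items()}
    )


def simulate_features(
    model: GaussianFeatureModel,
    n_per_symptom: int,
    seed: int,
    truncate: bool = True,
) -> list[FeatureRecord]:
    """Draw a balanced labelled feature set: ``n_per_symptom`` records per class.

    Each of the six features is drawn independently from its class-conditional
    normal.  Reproducible: a fixed seed yields byte-identical output.
    """
    if n_per_symptom < 1:
        raise ValueError("n_per_symptom must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[FeatureRecord] = []
    for symptom in SYMPTOM_IDS:
        cols = [
            model.draw(symptom, name, n_per_symptom, rng, truncate=truncate)
            for name in FEATURE_NAMES
        ]
        X = np.column_stack(cols)
        records.extend(FeatureRecord(row, label=symptom) for row in X)
    return records


@dataclass
class RhythmSpec:
    """Waveform-generator parameters for one rhythm class.

    ``premature_fraction`` is the probability that a beat is ectopic (early,
    and for ventricular ectopy wide/large); ``qrs_width_scale`` widens the QRS
    complex of ectopic (or, for VT, every) beats; ``fib_wave_amp`` adds a
    fibrillatory baseline oscillation (mV).
    """

    symptom: int
    heart_rate_bpm: float = 70.0
    premature_fraction: float = 0.0
    rr_jitter_sd_s: float = 0.02
    qrs_width_scale: float = 1.0
    fib_wave_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.symptom not in SYMPTOM_IDS:
            raise ValueError(f"invalid symptom ID {self.symptom}")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart rate must be positive")
        if not 0 <= self.premature_fraction <= 1:
            raise ValueError("premature_fraction must be in [0, 1]")


def default_rhythm_spec(symptom: int) -> RhythmSpec:
    """Stock generator settings per class (rates and ectopy typical of each)."""
    presets = {
        1: RhythmSpec(1, heart_rate_bpm=70, rr_jitter_sd_s=0.015),
        2: RhythmSpec(2, heart_rate_bpm=75, premature_fraction=0.25,
                      rr_jitter_sd_s=0.02),
        3: RhythmSpec(3, heart_rate_bpm=95, rr_jitter_sd_s=0.0,
                      fib_wave_amp=0.08),
        4: RhythmSpec(4, heart_rate_bpm=75, premature_fraction=0.25,
                      rr_jitter_sd_s=0.02, qrs_width_scale=2.5),
        5: RhythmSpec(5, heart_rate_bpm=160, rr_jitter_sd_s=0.01,
                      qrs_width_scale=2.5),
    }
    if symptom not in presets:
        raise ValueError(f"invalid symptom ID {symptom}")
    return presets[symptom]


# PQRST template: Gaussian bumps (offset from R in s, width in s, amplitude in
# mV).  Rough lead-II morphology; adequate for separability, not diagnosis.
_P = (-0.20, 0.020, 0.15)
_Q = (-0.035, 0.010, -0.10)
_R = (0.0, 0.012, 1.00)
_S = (0.035, 0.010, -0.18)
_T = (0.28, 0.060, 0.30)


def _add_beat(
    signal: np.ndarray,
    t: np.ndarray,
    center_s: float,
    qrs_scale: float,
    p_amp: float,
    r_gain: float,
) -> None:
    bumps = [
        (_P[0], _P[1], p_amp),
        (_Q[0], _Q[1] * qrs_scale, _Q[2] * r_gain),
        (_R[0], _R[1] * qrs_scale, _R[2] * r_gain),
        (_S[0], _S[1] * qrs_scale, _S[2] * r_gain),
        _T,
    ]
    for off, width, amp in bumps:
        if amp == 0.0:
            continue
        mu = center_s + off
        lo = np.searchsorted(t, mu - 6 * width)
        hi = np.searchsorted(t, mu + 6 * width)
        signal[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - mu) / width) ** 2)


def _rr_intervals(spec: RhythmSpec, duration_s: float, rng: np.random.Generator):
    """Beat times and per-beat ectopy flags for one record."""
    rr0 = 60.0 / spec.heart_rate_bpm
    times: list[float] = []
    ectopic: list[bool] = []
    t = rr0 / 2.0
    while t < duration_s:
        if spec.symptom == 3:
            # AFib: irregularly irregular, no repetitive pattern
            rr = rr0 * rng.uniform(0.6, 1.4)
            times.append(t)
            ectopic.append(True)
            t += rr
        elif spec.symptom == 5:
            # VT: sustained rapid run, every beat ventricular
            rr = rr0 * (1.0 + rng.normal(0.0, spec.rr_jitter_sd_s / rr0))
            times.append(t)
            ectopic.append(True)
            t += max(rr, 0.2)
        elif spec.premature_fraction > 0 and rng.random() < spec.premature_fraction:
            # premature complex: early beat followed by a compensatory pause
            times.append(t)
            ectopic.append(True)
            t += rr0 * 0.65
            if t < duration_s:
                times.append(t)
                ectopic.append(False)
            t += rr0 * 1.2
        else:
            rr = rr0 * (1.0 + rng.normal(0.0, spec.rr_jitter_sd_s / rr0))
            times.append(t)
            ectopic.append(False)
            t += max(rr, 0.25)
    return times, ectopic


def simulate_ecg(
    spec: RhythmSpec,
    duration_s: float = 30.0,
    fs: float = 360.0,
    seed: int = 0,
) -> ECGRecord:
    """Template-based synthetic single-lead ECG for one rhythm class.

    NSR: regular RR with P waves.  APC: occasional early narrow beats.
    AFib: irregular RR, no P waves, fibrillatory baseline.  VPC: occasional
    early wide large beats.  VT: sustained wide-QRS run above 120 bpm.
    Annotations mark the characteristic beats (every beat for NSR/AFib/VT,
    the ectopic beats for APC/VPC).  Reproducible under a fixed seed.
    """
    if duration_s < 3.0:
        raise ValueError("duration must be >= 3 s")
    rng = np.random.default_rng(seed)
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    signal = np.zeros(n)
    beat_times, ectopic = _rr_intervals(spec, duration_s, rng)
    annotations: list[tuple[float, int]] = []
    for bt, ect in zip(beat_times, ectopic):
        if spec.symptom in (3, 5):
            p_amp, qrs, gain = 0.0, spec.qrs_width_scale, 1.2 if spec.symptom == 5 else 1.0
        elif ect and spec.symptom == 4:
            p_amp, qrs, gain = 0.0, spec.qrs_width_scale, 1.5
        elif ect and spec.symptom == 2:
            p_amp, qrs, gain = 0.10, 1.0, 0.9
        else:
            p_amp, qrs, gain = _P[2], 1.0, 1.0
        _add_beat(signal, t, bt, qrs, p_amp, gain)
        labelled = ect or spec.symptom == 1
        if labelled and bt <= duration_s:
            annotations.append((round(bt, 6), spec.symptom))
    if spec.fib_wave_amp > 0:
        # coarse fibrillatory waves around 6 Hz with wandering phase
        phase = np.cumsum(rng.normal(2 * np.pi * 6 / fs, 0.01, size=n))
        signal += spec.fib_wave_amp * np.sin(phase)
    signal += rng.normal(0.0, 0.01, size=n)  # measurement noise floor
    rec_id = f"sim_{SYMPTOM_NAMES[spec.symptom].lower()}_{seed}"
    return ECGRecord(samples=signal, fs=fs, record_id=rec_id, annotations=annotations)
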