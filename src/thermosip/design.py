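"""Experimental design and ground-truth containers for the synthetic generator.

The stated world is a split-plot field trial: two management systems
(conventional ``CON`` vs organic ``ORG``) crossed with two cropping histories
(annual ``ANN`` vs annual-perennial ``PER``), four field replicates, and a
laboratory amendment factor (glucose at 500 ug C per g dry soil vs water).
Headspace gas is sampled 4, 12, 24, 36 and 48 h after amendment with the jars
flushed with CO2-free air after every sampling, so each reading is an interval
amount rather than a running total.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

MANAGEMENT_SYSTEMS = ("CON", "ORG")
CROPPING_HISTORIES = ("ANN", "PER")
AMENDMENTS = ("glucose", "water")
FRACTIONS = ("12C-light", "13C-light", "13C-heavy")

#: treatment keys in fixed (management, crop) order
TREATMENTS = tuple(
    (ms, crop) for ms in MANAGEMENT_SYSTEMS for crop in CROPPING_HISTORIES
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a simulated incubation experiment.

    Parameters
    ----------
    n_replicates : int
        Field replicates per treatment (default 4, >= 2).
    glucose_c_rate : float
        Glucose-C added, ug C per g dry soil (default 500).
    sampling_times_h : tuple of float
        Flush/sample schedule in hours, strictly increasing.
    duration_h : float
        Length of the incubation and calorimetry record, hours.
    """

    management_systems: tuple[str, ...] = MANAGEMENT_SYSTEMS
    cropping_histories: tuple[str, ...] = CROPPING_HISTORIES
    n_replicates: int = 4
    amendments: tuple[str, ...] = AMENDMENTS
    glucose_c_rate: float = 500.0
    sampling_times_h: tuple[float, ...] = (4.0, 12.0, 24.0, 36.0, 48.0)
    duration_h: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.sampling_times_h, dtype=float)
        if times.ndim != 1 or len(times) < 1:
            raise ValueError("sampling_times_h must be a non-empty sequence")
        if np.any(np.diff(times) <= 0) or times[0] <= 0:
            raise ValueError("sampling_times_h must be strictly increasing and positive")
        if times[-1] > self.duration_h:
            raise ValueError("last sampling time must not exceed duration_h")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.glucose_c_rate <= 0:
            raise ValueError("glucose_c_rate must be positive")

    def units(self) -> list[dict]:
        """Enumerate experimental units (one soil x amendment each)."""
        out = []
        for ms in self.management_systems:
            for crop in self.cropping_histories:
                for rep in range(1, self.n_replicates + 1):
                    for amendment in self.amendments:
                        out.append(
                            {
                                "unit_id": f"{ms}-{crop}-r{rep}-{amendment}",
                                "management": ms,
                                "crop": crop,
                                "replicate": rep,
                                "amendment": amendment,
                            }
                        )
        return out


# Default per-treatment truth: 48-h cumulative heats (J g-1), basal respiration
# (ug CO2-C g-1 per 48 h), glucose-derived CO2-C (ug g-1) and primed CO2-C
# (ug g-1) set to the published treatment means of the field trial this
# generator emulates.
_DEFAULT_TREATMENT_TRUTH = {
    # (management, crop): (Q_control, Q_glucose, R_basal_48h, R_glucose, R_primed)
    ("CON", "ANN"): (1.76, 7.47, 37.4, 172.5, 38.2),
    ("CON", "PER"): (1.54, 7.41, 31.2, 173.6, 33.4),
    ("ORG", "ANN"): (1.18, 7.01, 26.1, 168.8, 34.7),
    ("ORG", "PER"): (1.22, 6.86, 26.9, 168.0, 35.2),
}


def _default_q_control() -> dict:
    return {k: v[0] for k, v in _DEFAULT_TREATMENT_TRUTH.items()}


def _default_q_glucose() -> dict:
    return {k: v[1] for k, v in _DEFAULT_TREATMENT_TRUTH.items()}


def _default_basal() -> dict:
    return {k: v[2] for k, v in _DEFAULT_TREATMENT_TRUTH.items()}


def _default_fraction_respired(rate: float = 500.0) -> dict:
    return {k: v[3] / rate for k, v in _DEFAULT_TREATMENT_TRUTH.items()}


def _default_priming() -> dict:
    return {k: v[4] / v[2] for k, v in _DEFAULT_TREATMENT_TRUTH.items()}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth a simulated experiment is generated from.

    All per-treatment mappings are keyed by ``(management, crop)``.

    Attributes
    ----------
    q_control, q_glucose : mapping
        True 48-h cumulative heats, J per g dry soil.
    basal_respiration : mapping
        True basal (water-control) CO2-C over the incubation, ug C g-1.
    fraction_respired : mapping
        Fraction of added glucose-C respired within the incubation, in [0, 1].
    priming_coefficient : mapping
        Primed SOM-derived CO2-C as a fraction of basal CO2-C, >= 0.
    x_glucose, x_soil : float
        13C atom fractions of the labelled glucose and of unlabelled
        (SOM-derived) CO2; 0 < x_soil < x_glucose < 1.
    glucose_half_life_h : float
        Half-life of the respirable glucose pool (first-order kinetics).
    pulse_shape, pulse_scale_h : float
        Gamma parameters of the glucose heat pulse (mode (shape-1)*scale).
    enriched_taxa : mapping
        management system -> tuple of OTU ids planted as glucose utilizers.
    enrichment_log2fc : float
        Planted log2 fold-change of enriched taxa, 13C-heavy vs 13C-light.
    power_noise_sd : float
        Additive Gaussian noise on power readings, uW g-1.
    co2_noise_sd : float
        Additive Gaussian noise on interval CO2-C masses, ug C g-1.
    abundance_noise_sd : float
        Additive Gaussian noise on measured atom fractions.
    """

    q_control: Mapping = field(default_factory=_default_q_control)
    q_glucose: Mapping = field(default_factory=_default_q_glucose)
    basal_respiration: Mapping = field(default_factory=_default_basal)
    fraction_respired: Mapping = field(default_factory=_default_fraction_respired)
    priming_coefficient: Mapping = field(default_factory=_default_priming)
    x_glucose: float = 0.195
    x_soil: float = 0.0108
    glucose_half_life_h: float = 10.0
    pulse_shape: float = 3.0
    pulse_scale_h: float = 5.5
    enriched_taxa: Mapping = field(default_factory=dict)
    enrichment_log2fc: float = 2.0
    power_noise_sd: float = 0.5
    co2_noise_sd: float = 1.0
    abundance_noise_sd: float = 0.0005

    def __post_init__(self) -> None:
        if not (0.0 < self.x_soil < self.x_glucose < 1.0):
            raise ValueError("atom fractions must satisfy 0 < x_soil < x_glucose < 1")
        for key, frac in dict(self.fraction_respired).items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction_respired[{key}] outside [0, 1]")
        for key, p in dict(self.priming_coefficient).items():
            if p < 0:
                raise ValueError(f"priming_coefficient[{key}] must be >= 0")
        for sd in (self.power_noise_sd, self.co2_noise_sd, self.abundance_noise_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")

    def with_noise(self, power=0.0, co2=0.0, abundance=0.0) -> "SyntheticTruth":
        """Return a copy with the given noise standard deviations."""
        d = asdict(self)
        d.update(power_noise_sd=power, co2_noise_sd=co2, abundance_noise_sd=abundance)
        d["q_control"] = dict(self.q_control)
        d["q_glucose"] = dict(self.q_glucose)
        d["basal_respiration"] = dict(self.basal_respiration)
        d["fraction_respired"] = dict(self.fraction_respired)
        d["priming_coefficient"] = dict(self.priming_coefficient)
        d["enriched_taxa"] = dict(self.enriched_taxa)
        return SyntheticTruth(**d)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one integer seed.

    Every stochastic output of the generator draws from a stream keyed by the
    file type / stage name, so adding noise to one output never perturbs the
    draws of another.
    """
    digest = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, digest])
    return np.random.default_rng(ss)
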