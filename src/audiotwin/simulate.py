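"""Synthetic twin cohorts with known variance-component structure.

The generator draws, per subject, latent standard-normal traits built from
additive-genetic (A), common-environment (C) and unique-environment (E)
factors.  A factors correlate 1 across MZ co-twins and 0.5 across DZ
co-twins; C is fully shared within a pair; E is independent.  Two audiogram
traits drive the thresholds: an overall *level* trait and a high-frequency
*slope* trait.  A third latent trait produces the true speech-reception
threshold (SRT); its A and E factors are mixed with the level trait's
factors to achieve target cross-trait correlations ``r_a`` and ``r_e``
exactly in expectation.

Threshold at frequency ``f`` for ear ``ear``::

    thr = mean_profile[f] + age_slope[f] * (age - 60)
          + size_loadings[f] * level + slope_loadings[f] * slope
          + Normal(0, ear_noise_sd)

optionally rounded to the nearest 5 dB (audiometric convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from audiotwin.cohort import SubjectRecord, TwinCohort

logger = logging.getLogger(__name__)

DEFAULT_FREQS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

#: Illustrative defaults only: the generating age trend and loadings are not
#: estimated from any real cohort.
DEFAULT_MEAN_PROFILE = (12.0, 10.0, 10.0, 12.0, 16.0, 28.0, 45.0)
DEFAULT_AGE_SLOPE = (0.20, 0.20, 0.25, 0.30, 0.45, 0.70, 0.90)
DEFAULT_SIZE_LOADINGS = (6.0, 6.0, 6.0, 6.0, 6.0, 6.0, 6.0)
DEFAULT_SLOPE_LOADINGS = (-5.0, -4.0, -2.5, 0.0, 2.5, 4.0, 6.0)

LATENT_TRAITS = ("level", "slope", "srt")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _check_simplex(name: str, triple: tuple[float, float, float]) -> None:
    a2, c2, e2 = triple
    if min(a2, c2, e2) < 0:
        raise ConfigurationError(f"{name}: variance components must be non-negative")
    if abs(a2 + c2 + e2 - 1.0) > 1e-12:
        raise ConfigurationError(f"{name}: (a2, c2, e2) must sum to 1, got {a2 + c2 + e2!r}")


@dataclass
class SimConfig:
    """Generating parameters for a synthetic twin cohort."""

    n_mz_pairs: int = 250
    n_dz_pairs: int = 250
    n_singletons: int = 20
    age_range: tuple[float, float] = (41.0, 86.0)
    freqs: tuple[float, ...] = DEFAULT_FREQS
    mean_profile: tuple[float, ...] = DEFAULT_MEAN_PROFILE
    age_slope: tuple[float, ...] = DEFAULT_AGE_SLOPE
    size_loadings: tuple[float, ...] = DEFAULT_SIZE_LOADINGS
    slope_loadings: tuple[float, ...] = DEFAULT_SLOPE_LOADINGS
    var_components: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "level": (0.7, 0.0, 0.3),
            "slope": (0.6, 0.0, 0.4),
            "srt": (0.7, 0.0, 0.3),
        }
    )
    #: (mean SRT dB, SD dB, r_a, r_e) linking the SRT trait to the audiogram
    #: *level* factors.
    srt_params: tuple[float, float, float, float] = (-10.2, 2.2, -0.67, -0.20)
    #: Measurement noise added to the recorded snr column (0 = record the
    #: true SRT; the staircase module provides a behavioural alternative).
    srt_measure_sd: float = 0.0
    ear_noise_sd: float = 3.0
    round_to_5db: bool = True
    #: Audiometer floor in dB HL (thresholds clipped from below); None disables.
    floor_db: float | None = -10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0 or self.n_singletons < 0:
            raise ConfigurationError("pair/singleton counts must be non-negative")
        if self.n_mz_pairs + self.n_dz_pairs + self.n_singletons <= 0:
            raise ConfigurationError("cohort would be empty")
        freqs = tuple(self.freqs)
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ConfigurationError("freqs must be strictly increasing")
        nf = len(freqs)
        for name in ("mean_profile", "age_slope", "size_loadings", "slope_loadings"):
            if len(getattr(self, name)) != nf:
                raise ConfigurationError(f"{name} must have one entry per frequency")
        for trait in LATENT_TRAITS:
            if trait not in self.var_components:
                raise ConfigurationError(f"var_components missing trait {trait!r}")
            _check_simplex(trait, tuple(self.var_components[trait]))
        _, sd, r_a, r_e = self.srt_params
        if sd < 0:
            raise ConfigurationError("SRT standard deviation must be non-negative")
        if abs(r_a) > 1 or abs(r_e) > 1:
            raise ConfigurationError("|r_a| and |r_e| must be <= 1")
        if self.var_components["srt"][1] != 0.0:
            raise ConfigurationError("srt trait must have c2 = 0 (AE generator)")
        if self.ear_noise_sd < 0 or self.srt_measure_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        lo, hi = self.age_range
        if hi < lo:
            raise ConfigurationError("age_range must be (low, high)")


def _ace_factors(rng: np.random.Generator, n_mz: int, n_dz: int, n_single: int):
    """Raw A/C/E standard-normal factors with twin sharing structure.

    Returns dict with keys 'A', 'C', 'E', each a pair of arrays
    (twin1, twin2) of length n_mz + n_dz + n_single; the second member of a
    singleton "pair" is unused.
    """
    n = n_mz + n_dz + n_single
    # A: MZ identical; DZ correlate 0.5 via a shared + unique split.
    a_mz = rng.standard_normal(n_mz)
    dz_shared = rng.standard_normal(n_dz)
    dz_u1 = rng.standard_normal(n_dz)
    dz_u2 = rng.standard_normal(n_dz)
    a_single = rng.standard_normal(n_single)
    s = np.sqrt(0.5)
    a1 = np.concatenate([a_mz, s * dz_shared + s * dz_u1, a_single])
    a2 = np.concatenate([a_mz, s * dz_shared + s * dz_u2, rng.standard_normal(n_single)])
    c = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    return {"A": (a1, a2), "C": (c, c), "E": (e1, e2)}


def simulate_cohort(config: SimConfig) -> TwinCohort:
    """Generate a :class:`TwinCohort` under ``config``.

    Latent factor values are retained per subject in ``latent_truth`` for
    recovery tests; no estimator in this package reads them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_mz, n_dz, n_single = config.n_mz_pairs, config.n_dz_pairs, config.n_singletons
    n_units = n_mz + n_dz + n_single

    factors = {t: _ace_factors(rng, n_mz, n_dz, n_single) for t in LATENT_TRAITS}

    # Cross-trait mixing: SRT's effective A/E factors share variance with the
    # level trait's A/E factors at exactly r_a / r_e.
    _, _, r_a, r_e = config.srt_params
    mixed_srt = {}
    for comp, r in (("A", r_a), ("E", r_e)):
        lev1, lev2 = factors["level"][comp]
        own1, own2 = factors["srt"][comp]
        w = np.sqrt(1.0 - r * r)
        mixed_srt[comp] = (r * lev1 + w * own1, r * lev2 + w * own2)
    factors["srt"]["A"] = mixed_srt["A"]
    factors["srt"]["E"] = mixed_srt["E"]

    # Combine into unit-variance latent traits per twin slot.
    latent: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for trait in LATENT_TRAITS:
        a2, c2, e2 = config.var_components[trait]
        wa, wc, we = np.sqrt(a2), np.sqrt(c2), np.sqrt(e2)
        vals = []
        for slot in (0, 1):
            vals.append(
                wa * factors[trait]["A"][slot]
                + wc * factors[trait]["C"][slot]
                + we * factors[trait]["E"][slot]
            )
        latent[trait] = tuple(vals)

    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n_units)

    mean_profile = np.asarray(config.mean_profile, dtype=float)
    age_slope = np.asarray(config.age_slope, dtype=float)
    size_load = np.asarray(config.size_loadings, dtype=float)
    slope_load = np.asarray(config.slope_loadings, dtype=float)
    srt_mean, srt_sd, _, _ = config.srt_params

    zygosities = ["MZ"] * n_mz + ["DZ"] * n_dz + ["singleton"] * n_single
    pair_ids = (
        [f"MZ{i + 1:04d}" for i in range(n_mz)]
        + [f"DZ{i + 1:04d}" for i in range(n_dz)]
        + [f"SG{i + 1:04d}" for i in range(n_single)]
    )

    records: list[SubjectRecord] = []
    subject_counter = 0
    for unit in range(n_units):
        zyg = zygosities[unit]
        slots = (0,) if zyg == "singleton" else (0, 1)
        for slot in slots:
            subject_counter += 1
            level = latent["level"][slot][unit]
            slope = latent["slope"][slot][unit]
            srt_latent = latent["srt"][slot][unit]
            base = (
                mean_profile
                + age_slope * (ages[unit] - 60.0)
                + size_load * level
                + slope_load * slope
            )
            thr_l = base + rng.normal(0.0, config.ear_noise_sd, size=base.shape)
            thr_r = base + rng.normal(0.0, config.ear_noise_sd, size=base.shape)
            if config.floor_db is not None:
                thr_l = np.maximum(thr_l, config.floor_db)
                thr_r = np.maximum(thr_r, config.floor_db)
            if config.round_to_5db:
                thr_l = np.round(thr_l / 5.0) * 5.0
                thr_r = np.round(thr_r / 5.0) * 5.0
            srt_true = srt_mean + srt_sd * srt_latent
            snr = srt_true + (
                rng.normal(0.0, config.srt_measure_sd) if config.srt_measure_sd > 0 else 0.0
            )
            truth = {
                "lat_level": level,
                "lat_slope": slope,
                "lat_srt": srt_latent,
                "lat_level_A": factors["level"]["A"][slot][unit],
                "lat_level_E": factors["level"]["E"][slot][unit],
                "lat_srt_A": factors["srt"]["A"][slot][unit],
                "lat_srt_E": factors["srt"]["E"][slot][unit],
                "srt_true": srt_true,
            }
            records.append(
                SubjectRecord(
                    subject_id=f"S{subject_counter:05d}",
                    pair_id=pair_ids[unit],
                    zygosity=zyg,
                    age=float(ages[unit]),
                    sex="F",
                    thresholds_left=thr_l,
                    thresholds_right=thr_r,
                    snr=float(snr),
                    latent_truth=truth,
                )
            )
    return TwinCohort(
        records=records,
        freqs=tuple(config.freqs),
        config=config,
        provenance=f"simulated with seed {config.seed}",
    )


def repeat_measurement(
    cohort: TwinCohort, noise_sd: float, seed: int = 0
) -> pd.DataFrame:
    """Re-test each subject once: paired (first, second) SNR scores.

    ``second = true SRT + Normal(0, noise_sd)``; subjects without an SNR are
    skipped with a warning.  The result feeds Bland-Altman/Pitman analyses.
    """
    rng = np.random.default_rng(seed)
    rows = []
    skipped = 0
    for rec in cohort.records:
        if rec.snr is None:
            skipped += 1
            continue
        base = rec.latent_truth["srt_true"] if rec.latent_truth else rec.snr
        rows.append(
            {
                "subject_id": rec.subject_id,
                "first": rec.snr,
                "second": base + rng.normal(0.0, noise_sd),
            }
        )
    if skipped:
        logger.warning("repeat_measurement: skipped %d subjects without SNR", skipped)
    if not rows:
        logger.warning("repeat_measurement: empty cohort or no SNR values")
        return pd.DataFrame(columns=["subject_id", "first", "second"])
    return pd.DataFrame(rows)
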