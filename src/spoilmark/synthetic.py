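"""Synthetic LC-MS feature tables emulating a raw-milk storage time-course.

The generator reproduces the statistical structure the downstream analysis
assumes: a 10-day x 5-replicate in-solution study in which a small minority
of features drift monotonically with storage day (the spoilage markers),
replicate-to-replicate multiplicative noise, per-table m/z and retention
time jitter within the merge tolerances, features that only occur in blank
runs, and per-gel-band in-gel subsets that share part of their features with
the in-solution set.

The intensity model is linear in day with log-normal replicate noise: an
up-marker's expected intensity at day *d* is ``base * (1 + s * (d - 1))``
and a down-marker's ``base * max(eps, 1 - s * (d - 1))`` with trend strength
*s* per day and floor ``eps = 0.01``; non-marker features have no day
dependence.  Dropout sets an intensity to 0, modelling a feature the
detector failed to find in that run.  Optionally, marker features receive
m/z values of real theoretical peptides (digest + modification variants of
supplied proteins) so that the identification stage can re-discover the
planted ground truth end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import (CleavageRules, ModificationSet, ProteinRecord,
                        TheoreticalPeptide, build_database, default_modifications,
                        theoretical_mz)
from .exceptions import ConfigurationError
from .features import FeatureTable

DOWN_FLOOR = 0.01

MZ_RANGE = (150.0, 1200.0)
#: Planted peptides stay in the precursor range typical of tryptic peptides;
#: the floor also keeps the 0.002% identification window at >= 4 sd of the
#: default m/z jitter at every charge, so planted markers are recoverable by
#: construction rather than by chance.
PLANT_MZ_RANGE = (400.0, 1200.0)
RT_RANGE = (60.0, 900.0)
CHARGES = (1, 2, 3)


@dataclass(frozen=True)
class BandSpec:
    """One SDS-PAGE band: label, feature count, overlap with the in-solution set."""

    label: str
    n_features: int = 80
    overlap_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_features < 0:
            raise ConfigurationError(f"band {self.label!r}: n_features must be >= 0")
        if not 0 <= self.overlap_fraction <= 1:
            raise ConfigurationError(
                f"band {self.label!r}: overlap_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the simulated storage experiment.

    Defaults encode the modelled study: ten storage days, five replicate
    preparations per day, a minority of monotone marker features among a
    background of day-independent ones.
    """

    n_days: int = 10
    n_replicates: int = 5
    n_features: int = 500
    n_markers_up: int = 5
    n_markers_down: int = 5
    trend_strength: float = 0.10        # fractional intensity change per day
    noise_cv: float = 0.2               # coefficient of variation of replicate noise
    mz_jitter_sd: float = 0.002         # Da
    rt_jitter_sd: float = 0.5           # seconds
    dropout_prob: float = 0.05
    n_blank_features: int = 25
    bands: tuple[BandSpec, ...] = (BandSpec("2"), BandSpec("5"), BandSpec("8"))
    seed: int = 1

    def __post_init__(self) -> None:
        counts = {"n_days": self.n_days, "n_replicates": self.n_replicates,
                  "n_features": self.n_features, "n_markers_up": self.n_markers_up,
                  "n_markers_down": self.n_markers_down,
                  "n_blank_features": self.n_blank_features}
        for name, v in counts.items():
            if v < 0 or (name in ("n_days", "n_replicates", "n_features") and v < 1):
                raise ConfigurationError(f"{name} must be a positive count, got {v}")
        if self.n_markers_up + self.n_markers_down > self.n_features:
            raise ConfigurationError("more markers than features")
        if not 0 <= self.dropout_prob <= 1:
            raise ConfigurationError(f"dropout_prob must be in [0, 1], got {self.dropout_prob}")
        for name, v in (("trend_strength", self.trend_strength),
                        ("noise_cv", self.noise_cv),
                        ("mz_jitter_sd", self.mz_jitter_sd),
                        ("rt_jitter_sd", self.rt_jitter_sd)):
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class PlantedPeptide:
    """Ground-truth assignment of a marker feature to a theoretical peptide."""

    feature_id: str
    peptide: TheoreticalPeptide
    charge: int
    mz_theoretical: float


@dataclass
class GroundTruth:
    """What the generator planted, for closed-loop validation."""

    marker_directions: dict[str, str] = field(default_factory=dict)   # id -> "up"/"down"
    peptide_assignments: dict[str, PlantedPeptide] = field(default_factory=dict)
    blank_ids: list[str] = field(default_factory=list)
    band_overlap: dict[str, list[str]] = field(default_factory=dict)  # band -> shared ids
    true_mz: dict[str, float] = field(default_factory=dict)
    true_rt: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Planting peptides
# ---------------------------------------------------------------------------

def plant_peptide_features(config: SyntheticConfig,
                           proteins: Sequence[ProteinRecord],
                           rules: CleavageRules | None = None,
                           mods: ModificationSet | None = None) -> GroundTruth:
    """Assign a random theoretical peptide (at charge 1-3) to every marker.

    The assigned m/z is the exact theoretical value; the generator adds the
    configured jitter when it writes the table, so that re-identification at
    the matching tolerance succeeds whenever the jitter is small against it.
    """
    if not proteins:
        raise ConfigurationError("at least one digestible protein is required")
    database = build_database(proteins, rules, mods if mods is not None
                              else default_modifications())
    candidates = []
    for pep in database:
        for z in CHARGES:
            mz = theoretical_mz(pep.neutral_mass, z)
            if PLANT_MZ_RANGE[0] <= mz <= PLANT_MZ_RANGE[1]:
                candidates.append((pep, z, mz))
    if not candidates:
        raise ConfigurationError("digest produced no peptides in the m/z range")
    rng = np.random.default_rng([config.seed, 101])
    truth = GroundTruth()
    n_markers = config.n_markers_up + config.n_markers_down
    picks = rng.integers(0, len(candidates), size=n_markers)
    for i, pick in enumerate(picks):
        pep, z, mz = candidates[int(pick)]
        fid = _marker_id(i)
        truth.peptide_assignments[fid] = PlantedPeptide(
            feature_id=fid, peptide=pep, charge=z, mz_theoretical=mz)
    return truth


def _marker_id(i: int) -> str:
    return f"M{i:04d}"


# ---------------------------------------------------------------------------
# Time-course generation
# ---------------------------------------------------------------------------

def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv ** 2)
    return np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=size))


def _day_profile(direction: str, s: float, days: np.ndarray) -> np.ndarray:
    if direction == "up":
        return 1.0 + s * (days - 1)
    return np.maximum(DOWN_FLOOR, 1.0 - s * (days - 1))


def generate_timecourse(config: SyntheticConfig,
                        proteins: Sequence[ProteinRecord] | None = None,
                        rules: CleavageRules | None = None,
                        mods: ModificationSet | None = None,
                        ) -> tuple[FeatureTable, GroundTruth]:
    """Generate the in-solution storage time-course and its ground truth.

    The table has ``n_days * n_replicates`` samples.  The first
    ``n_markers_up + n_markers_down`` feature ids (``M0000``, ...) are the
    planted markers; when ``proteins`` are supplied their m/z values come
    from real theoretical peptides via :func:`plant_peptide_features`.
    Identical configs (same seed) produce identical tables.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_markers = config.n_markers_up + config.n_markers_down
    n = config.n_features

    if proteins is not None and n_markers > 0:
        truth = plant_peptide_features(config, proteins, rules, mods)
    else:
        truth = GroundTruth()

    feature_ids = [_marker_id(i) for i in range(n_markers)]
    feature_ids += [f"F{i:05d}" for i in range(n - n_markers)]
    true_mz = rng.uniform(*MZ_RANGE, size=n)
    true_rt = rng.uniform(*RT_RANGE, size=n)
    charges = rng.choice(CHARGES, size=n)
    for i in range(n_markers):
        fid = feature_ids[i]
        direction = "up" if i < config.n_markers_up else "down"
        truth.marker_directions[fid] = direction
        planted = truth.peptide_assignments.get(fid)
        if planted is not None:
            true_mz[i] = planted.mz_theoretical
            charges[i] = planted.charge
    truth.true_mz.update(zip(feature_ids, true_mz))
    truth.true_rt.update(zip(feature_ids, true_rt))

    days = np.repeat(np.arange(1, config.n_days + 1), config.n_replicates)
    reps = np.tile(np.arange(1, config.n_replicates + 1), config.n_days)
    sample_ids = [f"d{d:02d}r{r}" for d, r in zip(days, reps)]
    n_samples = len(sample_ids)

    base = 10 ** rng.uniform(4, 6, size=n)
    mean = np.tile(base, (n_samples, 1))
    for i in range(n_markers):
        direction = truth.marker_directions[feature_ids[i]]
        mean[:, i] = base[i] * _day_profile(direction, config.trend_strength, days)
    intensities = mean * _lognormal_noise(rng, config.noise_cv, mean.shape)
    if config.dropout_prob > 0:
        intensities[rng.random(mean.shape) < config.dropout_prob] = 0.0

    obs_mz = true_mz + rng.normal(0, config.mz_jitter_sd, size=n) if config.mz_jitter_sd else true_mz
    obs_rt = np.maximum(0.0, true_rt + (rng.normal(0, config.rt_jitter_sd, size=n)
                                        if config.rt_jitter_sd else 0.0))

    features = pd.DataFrame({"mz": obs_mz, "rt": obs_rt, "charge": charges},
                            index=pd.Index(feature_ids, name="feature_id"))
    samples = pd.DataFrame({"day": days, "replicate": reps,
                            "experiment": "in_solution", "band": None},
                           index=pd.Index(sample_ids, name="sample_id"))
    intens = pd.DataFrame(intensities, index=samples.index, columns=features.index)
    return FeatureTable(features, intens, samples), truth


# ---------------------------------------------------------------------------
# In-gel bands and blanks
# ---------------------------------------------------------------------------

def generate_ingel(config: SyntheticConfig, insolution: FeatureTable,
                   truth: GroundTruth,
                   labels: Sequence[str] | None = None,
                   ) -> dict[str, tuple[FeatureTable, FeatureTable]]:
    """Per-band in-gel tables plus their blank tables.

    Each band shares ``overlap_fraction`` of its features with the
    in-solution table (same underlying analyte: same true coordinates up to
    fresh jitter, same day trend); the planted markers are preferentially
    among the shared features, mirroring casein-band chemistry.  Band tables
    additionally contain the blank-only contaminant features, which the
    returned blank table allows eliminating.  The shared ids per band are
    recorded in ``truth.band_overlap``.
    """
    available = {b.label: b for b in config.bands}
    if labels is None:
        labels = [b.label for b in config.bands]
    unknown = [l for l in labels if l not in available]
    if unknown:
        raise ConfigurationError(f"unknown band label(s): {unknown}; "
                                 f"configured bands: {sorted(available)}")

    days = np.arange(1, config.n_days + 1)
    sol_ids = insolution.feature_ids

    # blank features are global to the in-gel experiment
    rng_blank = np.random.default_rng([config.seed, 7])
    blank_ids = [f"B{i:04d}" for i in range(config.n_blank_features)]
    blank_mz = rng_blank.uniform(*MZ_RANGE, size=config.n_blank_features)
    blank_rt = rng_blank.uniform(*RT_RANGE, size=config.n_blank_features)
    blank_base = 10 ** rng_blank.uniform(4, 5, size=config.n_blank_features)
    truth.blank_ids = list(blank_ids)
    for fid, mz, rt in zip(blank_ids, blank_mz, blank_rt):
        truth.true_mz[fid] = mz
        truth.true_rt[fid] = rt

    out: dict[str, tuple[FeatureTable, FeatureTable]] = {}
    for label in labels:
        spec = available[label]
        rng = np.random.default_rng([config.seed, 13, int(_band_key(label))])
        n_overlap = int(round(spec.overlap_fraction * spec.n_features))
        n_overlap = min(n_overlap, len(sol_ids))
        markers = [f for f in truth.marker_directions if f in set(sol_ids)]
        shared = markers[:n_overlap]
        remaining = [f for f in sol_ids if f not in set(shared)]
        if len(shared) < n_overlap:
            extra = rng.choice(len(remaining), size=n_overlap - len(shared), replace=False)
            shared = shared + [remaining[int(i)] for i in sorted(extra)]
        truth.band_overlap[label] = list(shared)

        n_private = spec.n_features - len(shared)
        private_ids = [f"G{label}_{i:04d}" for i in range(n_private)]
        private_mz = rng.uniform(*MZ_RANGE, size=n_private)
        private_rt = rng.uniform(*RT_RANGE, size=n_private)
        private_charge = rng.choice(CHARGES, size=n_private)

        ids = list(shared) + private_ids + blank_ids
        mz_true = np.concatenate([
            [truth.true_mz[f] for f in shared], private_mz, blank_mz]) if ids else np.empty(0)
        rt_true = np.concatenate([
            [truth.true_rt[f] for f in shared], private_rt, blank_rt]) if ids else np.empty(0)
        charge = np.concatenate([
            insolution.features.loc[shared, "charge"].to_numpy(int)
            if shared else np.empty(0, int),
            private_charge, _blank_charges(config)])
        # band-level attenuation: in-gel workups recover less material
        base = np.concatenate([
            0.5 * np.array([insolution.intensities[f].mean() or 1e4 for f in shared]),
            10 ** rng.uniform(4, 5.5, size=n_private), blank_base])

        mean = np.tile(base, (config.n_days, 1))
        for j, fid in enumerate(shared):
            direction = truth.marker_directions.get(fid)
            if direction:
                mean[:, j] = base[j] * _day_profile(direction, config.trend_strength, days)
        intens = mean * _lognormal_noise(rng, config.noise_cv, mean.shape)
        if config.dropout_prob > 0:
            intens[rng.random(mean.shape) < config.dropout_prob] = 0.0

        obs_mz = mz_true + (rng.normal(0, config.mz_jitter_sd, size=len(ids))
                            if config.mz_jitter_sd else 0.0)
        obs_rt = np.maximum(0.0, rt_true + (rng.normal(0, config.rt_jitter_sd, size=len(ids))
                                            if config.rt_jitter_sd else 0.0))
        sample_ids = [f"b{label}_d{d:02d}" for d in days]
        features = pd.DataFrame({"mz": obs_mz, "rt": obs_rt, "charge": charge.astype(int)},
                                index=pd.Index(ids, name="feature_id"))
        samples = pd.DataFrame({"day": days, "replicate": 1,
                                "experiment": "in_gel", "band": label},
                               index=pd.Index(sample_ids, name="sample_id"))
        band_table = FeatureTable(features,
                                  pd.DataFrame(intens, index=samples.index,
                                               columns=features.index),
                                  samples)

        blank_obs_mz = blank_mz + (rng.normal(0, config.mz_jitter_sd, size=len(blank_ids))
                                   if config.mz_jitter_sd else 0.0)
        blank_obs_rt = np.maximum(0.0, blank_rt +
                                  (rng.normal(0, config.rt_jitter_sd, size=len(blank_ids))
                                   if config.rt_jitter_sd else 0.0))
        blank_features = pd.DataFrame(
            {"mz": blank_obs_mz, "rt": blank_obs_rt,
             "charge": _blank_charges(config)},
            index=pd.Index(blank_ids, name="feature_id"))
        blank_samples = pd.DataFrame(
            {"day": 0, "replicate": np.arange(1, 4), "experiment": "blank", "band": None},
            index=pd.Index([f"blank{label}_{i}" for i in range(1, 4)], name="sample_id"))
        blank_int = blank_base * _lognormal_noise(rng, config.noise_cv, (3, len(blank_ids)))
        blank_table = FeatureTable(blank_features,
                                   pd.DataFrame(blank_int, index=blank_samples.index,
                                                columns=blank_features.index),
                                   blank_samples)
        out[label] = (band_table, blank_table)
    return out


def _band_key(label: str) -> int:
    return sum(ord(c) for c in str(label))


def _blank_charges(config: SyntheticConfig) -> np.ndarray:
    rng = np.random.default_rng([config.seed, 8])
    return rng.choice(CHARGES, size=config.n_blank_features)
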