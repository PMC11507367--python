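"""Feature tables and tolerance-based feature arithmetic.

An LC-MS *feature* is a consolidated signal characterised by a mass-to-charge
ratio (m/z, Th), a retention time (seconds) and an estimated charge state,
with one intensity per sample.  A :class:`FeatureTable` holds the feature
metadata, the samples x features intensity matrix and per-sample annotations
(storage day, replicate, experiment, gel band), mirroring the two-DataFrame
layout common in Python MS workflows.

The operations in this module are the bookkeeping half of the marker
workflow: merging near-duplicate features within absolute m/z and retention
time tolerances, eliminating features that also occur in blank runs,
matching features across experiments (in-solution vs in-gel), and
converting an (m/z, z) pair to its neutral monoisotopic mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParseError

logger = logging.getLogger(__name__)

#: Monoisotopic mass of the proton in Da.
PROTON_MASS = 1.007276

FEATURE_COLUMNS = ("mz", "rt", "charge")
SAMPLE_COLUMNS = ("day", "replicate", "experiment", "band")

EXPERIMENTS = ("in_solution", "in_gel", "blank")


@dataclass(frozen=True)
class Feature:
    """A single consolidated LC-MS signal."""

    id: str
    mz: float
    rt: float
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ConfigurationError(f"feature {self.id!r}: mz must be > 0, got {self.mz}")
        if self.rt < 0:
            raise ConfigurationError(f"feature {self.id!r}: rt must be >= 0, got {self.rt}")
        if self.charge < 0:
            raise ConfigurationError(f"feature {self.id!r}: charge must be >= 0, got {self.charge}")


@dataclass(frozen=True)
class MatchPair:
    """A cross-experiment feature pair within the matching tolerances."""

    feature_a: str
    feature_b: str
    dmz: float
    drt: float


class FeatureTable:
    """Feature metadata plus a samples x features intensity matrix.

    Parameters
    ----------
    features
        DataFrame indexed by unique feature id with columns ``mz``, ``rt``,
        ``charge``.
    intensities
        DataFrame indexed by sample id with one column per feature id,
        non-negative entries (0 encodes "not detected in this sample").
    samples
        DataFrame indexed by sample id with columns ``day``, ``replicate``,
        ``experiment`` and ``band`` (band is only meaningful for in-gel
        samples).
    """

    def __init__(self, features: pd.DataFrame, intensities: pd.DataFrame,
                 samples: pd.DataFrame) -> None:
        features = features.copy()
        intensities = intensities.copy()
        samples = samples.copy()
        features.index = features.index.astype(str)
        intensities.columns = intensities.columns.astype(str)

        if not features.index.is_unique:
            dupes = features.index[features.index.duplicated()].tolist()
            raise ParseError(f"duplicate feature ids: {dupes[:5]}")
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise ParseError(f"feature metadata missing columns: {missing}")
        if list(intensities.columns) != list(features.index):
            intensities = intensities.reindex(columns=features.index)
            if intensities.isna().any().any():
                raise ParseError("intensity matrix columns do not match feature ids")
        if list(intensities.index) != list(samples.index):
            raise ParseError("intensity matrix rows do not match sample ids")
        if (intensities.to_numpy() < 0).any():
            raise ParseError("intensities must be non-negative")
        if (features["mz"].to_numpy() <= 0).any():
            raise ParseError("all feature m/z values must be > 0")
        if (features["rt"].to_numpy() < 0).any():
            raise ParseError("all feature retention times must be >= 0")
        for col in SAMPLE_COLUMNS:
            if col not in samples.columns:
                samples[col] = None if col == "band" else 0

        self.features = features
        self.intensities = intensities
        self.samples = samples

    # -- basic protocol ---------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    def intensity_matrix(self) -> np.ndarray:
        """samples x features matrix as float ndarray."""
        return self.intensities.to_numpy(dtype=float)

    def subset(self, feature_ids: Sequence[str]) -> "FeatureTable":
        """Restrict to the given feature ids (order preserved)."""
        ids = [str(f) for f in feature_ids]
        return FeatureTable(self.features.loc[ids], self.intensities[ids], self.samples)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FeatureTable({self.n_features} features, {self.n_samples} samples)"

    def equals(self, other: "FeatureTable", rtol: float = 1e-9) -> bool:
        """Numeric equality within a relative tolerance (ids must match exactly)."""
        if self.feature_ids != other.feature_ids:
            return False
        if list(self.samples.index) != list(other.samples.index):
            return False
        for a, b in ((self.features[["mz", "rt"]], other.features[["mz", "rt"]]),
                     (self.intensities, other.intensities)):
            if not np.allclose(a.to_numpy(float), b.to_numpy(float), rtol=rtol, atol=0):
                return False
        return (self.features["charge"].to_numpy() == other.features["charge"].to_numpy()).all()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, samples_path: str | Path | None = None) -> FeatureTable:
    """Read a feature-table CSV (``feature_id,mz,rt,charge,<sample>,...``).

    One row per feature; every column after ``charge`` is a sample.  Sample
    annotations are read from ``samples_path`` when given (CSV with columns
    ``sample_id,day,replicate,experiment,band``); otherwise day/replicate are
    parsed from sample ids of the form ``d<day>r<replicate>`` where possible.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"feature_id": str})
    required = ["feature_id", "mz", "rt", "charge"]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in required]
    if df["feature_id"].duplicated().any():
        dup = df["feature_id"][df["feature_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate feature id {dup!r}")
    for col in ["mz", "rt", "charge"] + sample_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = numeric

    features = df.set_index("feature_id")[["mz", "rt", "charge"]]
    features["charge"] = features["charge"].astype(int)
    intensities = df.set_index("feature_id")[sample_cols].T
    intensities.index.name = "sample_id"

    if samples_path is not None:
        samples = pd.read_csv(samples_path, dtype={"sample_id": str, "band": str})
        if "sample_id" not in samples.columns:
            raise ParseError(f"{samples_path}: missing required column 'sample_id'")
        samples = samples.set_index("sample_id").reindex(intensities.index)
    else:
        samples = _samples_from_ids(intensities.index)
    return FeatureTable(features, intensities, samples)


def _samples_from_ids(sample_ids: Iterable[str]) -> pd.DataFrame:
    import re

    rows = []
    for sid in sample_ids:
        m = re.match(r".*d(\d+)r(\d+)$", str(sid))
        day, rep = (int(m.group(1)), int(m.group(2))) if m else (0, 0)
        rows.append({"sample_id": str(sid), "day": day, "replicate": rep,
                     "experiment": "in_solution", "band": None})
    return pd.DataFrame(rows).set_index("sample_id")


def write_feature_table(table: FeatureTable, path: str | Path,
                        samples_path: str | Path | None = None) -> None:
    """Write the CSV dialect read by :func:`read_feature_table`."""
    path = Path(path)
    out = table.features.copy()
    out.index.name = "feature_id"
    for sid in table.intensities.index:
        out[sid] = table.intensities.loc[sid].to_numpy()
    out.to_csv(path, float_format="%.10g")
    if samples_path is not None:
        samples = table.samples.copy()
        samples.index.name = "sample_id"
        samples.to_csv(samples_path)


# ---------------------------------------------------------------------------
# Tolerance-based operations
# ---------------------------------------------------------------------------

def _check_tolerances(mz_tol: float, rt_tol: float) -> None:
    if mz_tol < 0 or rt_tol < 0:
        raise ConfigurationError(
            f"tolerances must be non-negative, got mz_tol={mz_tol}, rt_tol={rt_tol}")


def merge_features(table: FeatureTable, mz_tol: float = 0.01,
                   rt_tol: float = 2.0) -> FeatureTable:
    """Merge near-duplicate features within absolute m/z and RT tolerances.

    Features are visited in order of descending total intensity; each unmerged
    seed absorbs every remaining feature within both tolerances of the seed's
    coordinates.  The merged feature carries the per-sample intensity sum, the
    intensity-weighted mean m/z and RT of its members, the seed's id and the
    charge of the highest-intensity member (the seed).  The pass is repeated
    until no further merge occurs, so the result is a fixed point: no two
    surviving features lie within both tolerances of each other, and
    ``merge(merge(T)) == merge(T)``.
    """
    _check_tolerances(mz_tol, rt_tol)
    current = table
    for _ in range(64):  # fixpoint reached after 1-2 passes in practice
        merged = _merge_pass(current, mz_tol, rt_tol)
        if merged.n_features == current.n_features:
            return merged
        current = merged
    return current  # pragma: no cover - pathological inputs only


def _merge_pass(table: FeatureTable, mz_tol: float, rt_tol: float) -> FeatureTable:
    mz = table.features["mz"].to_numpy(float)
    rt = table.features["rt"].to_numpy(float)
    charge = table.features["charge"].to_numpy(int)
    inten = table.intensity_matrix()  # samples x features
    totals = inten.sum(axis=0)
    ids = np.asarray(table.feature_ids)

    # stable order: descending total intensity, ties by id
    order = np.lexsort((ids, -totals))
    unmerged = np.ones(len(ids), dtype=bool)
    new_rows = []
    new_int_cols = []
    for i in order:
        if not unmerged[i]:
            continue
        members = unmerged & (np.abs(mz - mz[i]) <= mz_tol) & (np.abs(rt - rt[i]) <= rt_tol)
        unmerged[members] = False
        idx = np.flatnonzero(members)
        w = totals[idx]
        if w.sum() > 0:
            new_mz = float(np.average(mz[idx], weights=w))
            new_rt = float(np.average(rt[idx], weights=w))
        else:
            new_mz = float(mz[idx].mean())
            new_rt = float(rt[idx].mean())
        if len(set(charge[idx])) > 1:
            logger.warning("merge: charge conflict among %s; keeping charge %d of seed %s",
                           list(ids[idx]), charge[i], ids[i])
        new_rows.append({"feature_id": ids[i], "mz": new_mz, "rt": new_rt,
                         "charge": int(charge[i])})
        new_int_cols.append(inten[:, idx].sum(axis=1))

    features = pd.DataFrame(new_rows).set_index("feature_id")
    intensities = pd.DataFrame(
        np.column_stack(new_int_cols) if new_int_cols else np.empty((table.n_samples, 0)),
        index=table.intensities.index, columns=features.index)
    # restore original feature order for the survivors
    keep = [f for f in table.feature_ids if f in set(features.index)]
    return FeatureTable(features.loc[keep], intensities[keep], table.samples)


def subtract_blank(table: FeatureTable, blank: FeatureTable, mz_tol: float = 0.01,
                   rt_tol: float = 2.0) -> FeatureTable:
    """Drop every feature with a blank-run feature within both tolerances.

    Applying the operation twice equals applying it once, and the output
    features are always a subset of the input features.
    """
    _check_tolerances(mz_tol, rt_tol)
    if blank.n_features == 0:
        return table.subset(table.feature_ids)
    mz = table.features["mz"].to_numpy(float)[:, None]
    rt = table.features["rt"].to_numpy(float)[:, None]
    bmz = blank.features["mz"].to_numpy(float)[None, :]
    brt = blank.features["rt"].to_numpy(float)[None, :]
    hit = ((np.abs(mz - bmz) <= mz_tol) & (np.abs(rt - brt) <= rt_tol)).any(axis=1)
    keep = [f for f, h in zip(table.feature_ids, hit) if not h]
    logger.info("blank subtraction: %d of %d features eliminated",
                int(hit.sum()), table.n_features)
    return table.subset(keep)


def match_across(a: FeatureTable, b: FeatureTable, mz_tol: float = 0.01,
                 rt_tol: float = 5.0) -> list[MatchPair]:
    """Match each feature of ``a`` to its nearest feature of ``b`` within tolerances.

    A candidate pair must satisfy ``|dmz| <= mz_tol`` and ``|drt| <= rt_tol``.
    Among candidates the nearest neighbour by the scaled distance
    ``max(|dmz|/mz_tol, |drt|/rt_tol)`` is kept (ties broken by smaller
    ``|dmz|``, then by ``b`` id); each feature of ``a`` is paired at most once.
    """
    _check_tolerances(mz_tol, rt_tol)
    pairs: list[MatchPair] = []
    if a.n_features == 0 or b.n_features == 0:
        return pairs
    bmz = b.features["mz"].to_numpy(float)
    brt = b.features["rt"].to_numpy(float)
    bids = np.asarray(b.feature_ids)
    for fid, row in a.features.iterrows():
        dmz = bmz - float(row["mz"])
        drt = brt - float(row["rt"])
        ok = (np.abs(dmz) <= mz_tol) & (np.abs(drt) <= rt_tol)
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        with np.errstate(divide="ignore", invalid="ignore"):
            smz = np.where(np.abs(dmz[idx]) == 0, 0.0, np.abs(dmz[idx]) / mz_tol if mz_tol > 0 else np.inf)
            srt = np.where(np.abs(drt[idx]) == 0, 0.0, np.abs(drt[idx]) / rt_tol if rt_tol > 0 else np.inf)
        dist = np.maximum(smz, srt)
        ranking = sorted(range(len(idx)), key=lambda j: (dist[j], abs(dmz[idx[j]]), bids[idx[j]]))
        best = idx[ranking[0]]
        pairs.append(MatchPair(str(fid), str(bids[best]),
                               float(dmz[best]), float(drt[best])))
    return pairs


def neutral_mass(mz: float, charge: int) -> float:
    """Neutral monoisotopic mass ``M = (m/z - m_proton) * z`` in Da.

    ``charge`` must be >= 1; a feature with undetermined charge (0) cannot be
    converted and must be excluded upstream.
    """
    if charge < 1:
        raise ConfigurationError(f"charge must be >= 1 to compute a neutral mass, got {charge}")
    if not math.isfinite(mz):
        raise ConfigurationError(f"m/z must be finite, got {mz}")
    return (mz - PROTON_MASS) * charge


def table_from_records(records: Sequence[tuple[str, float, float, int]],
                       intensities: np.ndarray | None = None,
                       sample_meta: pd.DataFrame | None = None) -> FeatureTable:
    """Convenience constructor from ``(id, mz, rt, charge)`` tuples.

    When ``intensities`` is omitted a single all-ones pseudo-sample is used
    (sufficient for coordinate-only operations such as cross-matching).
    """
    features = pd.DataFrame(records, columns=["feature_id", "mz", "rt", "charge"])
    features = features.set_index("feature_id")
    if intensities is None:
        intensities = np.ones((1, len(features)))
    n_samples = intensities.shape[0]
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {"day": 0, "replicate": 0, "experiment": "in_solution", "band": None},
            index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id"))
    intens = pd.DataFrame(intensities, index=sample_meta.index, columns=features.index)
    return FeatureTable(features, intens, sample_meta)
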