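"""Optional adapter between external feature detectors and FeatureTable.

The core pipeline consumes consolidated feature tables and never performs
feature detection itself.  This module defines the boundary for workflows
that start from centroided mzML instead: a *feature detector* is any
callable that maps one run (an mzML path or anything else it understands)
to an iterable of :class:`DetectedFeature` records,

    detector(path) -> Iterable[DetectedFeature]

:func:`detect_feature_table` applies such a detector to one run per sample
and assembles the per-run detections into a single cross-sample
:class:`~spoilmark.features.FeatureTable`, consolidating detections of the
same analyte with the standard merge tolerances.  :func:`read_mzml_spectra`
exposes centroided spectra (via pyteomics) for detectors that want to be
implemented in Python.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .features import FeatureTable, merge_features

#: The documented detector interface: one run in, detected features out.
FeatureDetector = Callable[[str], Iterable["DetectedFeature"]]


@dataclass(frozen=True)
class DetectedFeature:
    """One detection reported by an external feature finder for one run."""

    mz: float
    rt: float
    intensity: float
    charge: int = 0


def read_mzml_spectra(path: str) -> Iterator[dict]:
    """Iterate the spectra of a (centroided) mzML file.

    Thin pass-through to :mod:`pyteomics.mzml`; each item is the standard
    pyteomics spectrum dict with ``m/z array`` / ``intensity array`` keys.
    Imported lazily so the core package has no mzML dependency.
    """
    from pyteomics import mzml  # optional dependency, only needed here

    yield from mzml.read(path)


def detect_feature_table(runs: Mapping[str, str], detector: FeatureDetector,
                         sample_meta: pd.DataFrame | None = None,
                         mz_tol: float = 0.01, rt_tol: float = 2.0) -> FeatureTable:
    """Run ``detector`` on one file per sample and consolidate the output.

    ``runs`` maps sample ids to detector inputs (typically mzML paths).
    Each detection becomes a provisional single-sample feature; detections
    of the same analyte across runs are then consolidated with the standard
    tolerance merge, yielding per-sample intensity sums and
    intensity-weighted coordinates.
    """
    if not runs:
        raise ConfigurationError("no runs supplied")
    sample_ids = list(runs)
    rows, columns = [], []
    for s_idx, (sample_id, source) in enumerate(runs.items()):
        for d_idx, det in enumerate(detector(source)):
            rows.append({"feature_id": f"{sample_id}:{d_idx}", "mz": det.mz,
                         "rt": det.rt, "charge": det.charge})
            col = np.zeros(len(sample_ids))
            col[s_idx] = det.intensity
            columns.append(col)
    if not rows:
        raise ConfigurationError("detector produced no features")
    features = pd.DataFrame(rows).set_index("feature_id")
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {"day": 0, "replicate": 0, "experiment": "in_solution", "band": None},
            index=pd.Index(sample_ids, name="sample_id"))
    intensities = pd.DataFrame(np.column_stack(columns), index=sample_meta.index,
                               columns=features.index)
    provisional = FeatureTable(features, intensities, sample_meta)
    return merge_features(provisional, mz_tol=mz_tol, rt_tol=rt_tol)
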