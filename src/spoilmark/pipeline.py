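"""Orchestration of the two published marker-selection workflows.

*In-solution*: merge near-duplicate features -> exploratory PCA (2
components, min-max scaled) -> two-class PLS-DA (fresh vs past-use-by, VIP >
1.5 pre-filter, 80/20 validation split) -> univariate-F top-k selection
against the storage day -> PLSR (component count chosen by held-out R^2)
-> VIP ranking -> top-N marker candidates with their intensity trend.

*In-gel*: per-band blank elimination -> per-band 2-component PLSR without a
validation split (the per-band tables are small) -> per-band VIP ranking.

*Cross-linking and identification*: each selected in-solution feature is
annotated with its nearest in-gel partner within (0.01 Th, 5 s), and
matched against the theoretical peptide database (digest + modifications)
at the relative mass tolerance.

Every constant is carried by :class:`PipelineConfig`; the defaults are the
published values of the workflow (merge 0.01 Th / 2 s, cross-match 0.01 Th /
5 s, k = 1000, VIP > 1.5, 80/20 split, top 50, 0.002% identification
tolerance, 2 in-gel components).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chemometrics as chem
from .digestion import (CleavageRules, Feature, ModificationSet, ProteinRecord,
                        build_database, default_modifications, match_features,
                        theoretical_mz)
from .exceptions import ConfigurationError, DegenerateClassError
from .features import (FeatureTable, match_across, merge_features, neutral_mass,
                       subtract_blank, table_from_records)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the workflow (defaults = published values)."""

    merge_mz_tol: float = 0.01          # Th, absolute
    merge_rt_tol: float = 2.0           # s, absolute
    crossmatch_mz_tol: float = 0.01     # Th
    crossmatch_rt_tol: float = 5.0      # s
    identification_rel_tol: float = 2e-5  # relative neutral-mass tolerance (0.002%)
    k_best: int = 1000                  # univariate-F pre-selection depth
    vip_threshold: float = 1.5          # PLS-DA VIP filter
    n_components_plsda: int = 2
    max_components: int = 10            # PLSR component search range
    ingel_components: int = 2
    train_frac: float = 0.8
    seed: int = 42
    use_by_boundary_day: int = 4        # days <= boundary count as fresh (96 h)
    top_n: int = 50                     # marker candidates reported
    scale_pls: bool = True              # autoscale predictors inside PLS stages

    def __post_init__(self) -> None:
        for name in ("merge_mz_tol", "merge_rt_tol", "crossmatch_mz_tol",
                     "crossmatch_rt_tol", "identification_rel_tol"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 1 <= self.max_components <= 50:
            raise ConfigurationError("max_components out of range")
        if self.k_best < 1 or self.top_n < 1:
            raise ConfigurationError("k_best and top_n must be >= 1")
        if not 0 < self.train_frac < 1:
            raise ConfigurationError("train_frac must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Results of one workflow run (all frames keyed by feature id)."""

    selected: pd.DataFrame = field(default_factory=pd.DataFrame)
    metrics: dict = field(default_factory=dict)
    confusion: pd.DataFrame | None = None
    crossmatch: pd.DataFrame = field(default_factory=pd.DataFrame)
    identifications: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_band: pd.DataFrame = field(default_factory=pd.DataFrame)
    stage_counts: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write every table and the metrics/provenance JSON to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in (("selected_features", self.selected),
                            ("crossmatch", self.crossmatch),
                            ("identifications", self.identifications),
                            ("per_band", self.per_band)):
            if frame is not None and len(frame):
                frame.to_csv(outdir / f"{name}.csv", index=False)
        if self.confusion is not None:
            self.confusion.to_csv(outdir / "confusion_matrix.csv")
        payload = {"metrics": _jsonable(self.metrics),
                   "stage_counts": self.stage_counts, "config": self.config}
        (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# In-solution workflow
# ---------------------------------------------------------------------------

def run_insolution(table: FeatureTable, config: PipelineConfig | None = None) -> RunReport:
    """Full in-solution marker selection; returns the top-N VIP features.

    Raises :class:`DegenerateClassError` when the samples cover only one of
    the two use-by classes (e.g. a single storage day).
    """
    if config is None:
        config = PipelineConfig()
    report = RunReport(config=config.to_dict())
    counts = report.stage_counts
    counts["input_features"] = table.n_features

    merged = merge_features(table, config.merge_mz_tol, config.merge_rt_tol)
    counts["merged_features"] = merged.n_features
    logger.info("merge: %d -> %d features", table.n_features, merged.n_features)

    X = merged.intensity_matrix()
    days = merged.samples["day"].to_numpy(int)
    ids = merged.feature_ids

    # exploratory PCA on min-max-scaled data (never gates later stages)
    scaled = chem.minmax_scale(X)
    pca_model = chem.pca(scaled, k=min(2, min(X.shape[0] - 1, X.shape[1])))
    report.metrics["pca_explained_variance_ratio"] = pca_model.explained_variance_ratio

    # PLS-DA branch: fresh vs past-use-by
    classes = chem.split_by_use_by(days, config.use_by_boundary_day)
    if len(set(classes)) < 2:
        raise DegenerateClassError(
            "all samples fall on one side of the use-by boundary; PLS-DA undefined")
    vip_sel = chem.vip_filter(X, classes, threshold=config.vip_threshold,
                              n_components=config.n_components_plsda, feature_ids=ids,
                              scale=config.scale_pls)
    counts["plsda_vip_filtered"] = len(vip_sel.selected)
    if len(vip_sel.selected) >= 2:
        da = chem.plsda(X[:, vip_sel.selected], classes,
                        n_components=config.n_components_plsda,
                        train_frac=config.train_frac, seed=config.seed,
                        scale=config.scale_pls)
        report.confusion = pd.DataFrame(da.confusion, index=da.classes, columns=da.classes)
        report.metrics["plsda_accuracy"] = da.accuracy
    else:  # pragma: no cover - tiny inputs
        logger.warning("VIP filter kept %d features; PLS-DA skipped", len(vip_sel.selected))

    # PLSR branch: F-selection then regression on the storage day
    k = config.k_best
    if k > len(ids):
        logger.warning("k_best=%d exceeds %d features; clipping", k, len(ids))
        k = len(ids)
    fsel = chem.f_select(X, days, k=k, feature_ids=ids)
    counts["f_selected"] = len(fsel.selected)
    Xk = X[:, fsel.selected]
    kept_ids = [ids[i] for i in fsel.selected]

    train, test = chem.train_test_split(range(len(days)), train_frac=config.train_frac,
                                        seed=config.seed)
    a_star, records = chem.choose_components(Xk, days, a_max=config.max_components,
                                             train_frac=config.train_frac, seed=config.seed,
                                             scale=config.scale_pls)
    model = chem.pls_fit(Xk[train], days[train], a_star, scale=config.scale_pls)
    mse, r2 = chem.evaluate(model, Xk[test], days[test])
    report.metrics.update({"plsr_components": a_star, "plsr_mse": mse, "plsr_r2": r2,
                           "component_search": records})

    vip = chem.vip_scores(model)
    order = np.argsort(-vip, kind="stable")
    top = order[:min(config.top_n, len(kept_ids))]
    rows = []
    for rank, j in enumerate(top, start=1):
        fid = kept_ids[j]
        rho = chem.spearman_trend(merged.intensities[fid].to_numpy(), days)
        rows.append({
            "feature_id": fid,
            "mz": float(merged.features.loc[fid, "mz"]),
            "rt": float(merged.features.loc[fid, "rt"]),
            "charge": int(merged.features.loc[fid, "charge"]),
            "vip": float(vip[j]),
            "rank": rank,
            "trend": "I" if rho >= 0 else "D",
            "spearman_rho": rho,
        })
    report.selected = pd.DataFrame(rows)
    counts["selected_features"] = len(rows)
    report._merged = merged  # kept for downstream cross-linking
    return report


# ---------------------------------------------------------------------------
# In-gel workflow
# ---------------------------------------------------------------------------

def run_ingel(band_tables: Mapping[str, FeatureTable],
              blank: FeatureTable | None = None,
              config: PipelineConfig | None = None) -> RunReport:
    """Per-band blank elimination + 2-component PLSR + VIP ranking.

    Bands with fewer than 3 samples are skipped with a warning.  No
    validation split is performed: the per-band tables are small and a split
    would erode the day coverage the regression needs.
    """
    if config is None:
        config = PipelineConfig()
    report = RunReport(config=config.to_dict())
    rows = []
    cleaned: dict[str, FeatureTable] = {}
    for label, band in band_tables.items():
        if band.n_samples < 3:
            logger.warning("band %s has %d samples; skipped", label, band.n_samples)
            continue
        cleaned_band = (subtract_blank(band, blank, config.merge_mz_tol, config.merge_rt_tol)
                        if blank is not None else band)
        report.stage_counts[f"band_{label}_features"] = cleaned_band.n_features
        cleaned[label] = cleaned_band
        days = cleaned_band.samples["day"].to_numpy(int)
        X = cleaned_band.intensity_matrix()
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        a = min(config.ingel_components, rank)
        if a < 1 or np.ptp(days) == 0:
            logger.warning("band %s: degenerate data; skipped", label)
            continue
        model = chem.pls_fit(X, days, a, scale=config.scale_pls)
        vip = chem.vip_scores(model)
        order = np.argsort(-vip, kind="stable")
        ids = cleaned_band.feature_ids
        for r, j in enumerate(order[:min(config.top_n, len(ids))], start=1):
            fid = ids[j]
            rho = chem.spearman_trend(cleaned_band.intensities[fid].to_numpy(), days)
            rows.append({"band": label, "feature_id": fid,
                         "mz": float(cleaned_band.features.loc[fid, "mz"]),
                         "rt": float(cleaned_band.features.loc[fid, "rt"]),
                         "charge": int(cleaned_band.features.loc[fid, "charge"]),
                         "vip": float(vip[j]), "rank": r,
                         "trend": "I" if rho >= 0 else "D"})
    report.per_band = pd.DataFrame(rows)
    report._cleaned_bands = cleaned
    return report


# ---------------------------------------------------------------------------
# Cross-linking and identification
# ---------------------------------------------------------------------------

def selected_as_table(selected: pd.DataFrame) -> FeatureTable:
    """Build a coordinate-only FeatureTable from a selected-features frame."""
    records = [(row["feature_id"], float(row["mz"]), float(row["rt"]), int(row["charge"]))
               for _, row in selected.iterrows()]
    return table_from_records(records)


def crosslink_and_identify(insolution_report: RunReport,
                           ingel_tables: Mapping[str, FeatureTable],
                           proteins: Sequence[ProteinRecord] | None = None,
                           config: PipelineConfig | None = None,
                           rules: CleavageRules | None = None,
                           mods: ModificationSet | None = None) -> RunReport:
    """Annotate selected features with in-gel partners and peptide matches.

    Cross-matching uses the (crossmatch_mz_tol, crossmatch_rt_tol)
    tolerances against each band table.  Identification digests ``proteins``
    (skipped with a warning when none are given) and reports every
    theoretical peptide within the relative mass tolerance, nearest first.
    """
    if config is None:
        config = PipelineConfig()
    report = RunReport(config=config.to_dict(),
                       selected=insolution_report.selected.copy(),
                       metrics=dict(insolution_report.metrics),
                       confusion=insolution_report.confusion,
                       stage_counts=dict(insolution_report.stage_counts))
    if report.selected.empty:
        return report
    sel_table = selected_as_table(report.selected)

    cross_rows = []
    for label, band in ingel_tables.items():
        for pair in match_across(sel_table, band, config.crossmatch_mz_tol,
                                 config.crossmatch_rt_tol):
            cross_rows.append({"feature_id": pair.feature_a, "band": label,
                               "partner_id": pair.feature_b,
                               "annotation": f"Band {label}—{pair.feature_b}",
                               "dmz": pair.dmz, "drt": pair.drt})
    report.crossmatch = pd.DataFrame(cross_rows)

    if proteins:
        database = build_database(proteins, rules,
                                  mods if mods is not None else default_modifications())
        feats = [Feature(id=r["feature_id"], mz=float(r["mz"]), rt=float(r["rt"]),
                         charge=int(r["charge"]))
                 for _, r in report.selected.iterrows()]
        matches = match_features(feats, database, rel_tol=config.identification_rel_tol)
        id_rows = []
        for m in matches:
            pep = m.peptide
            id_rows.append({
                "feature_id": m.feature_id,
                "mz": theoretical_mz(m.observed_neutral_mass, m.charge),
                "charge": m.charge,
                "sequence": pep.sequence,
                "protein": pep.protein,
                "start": pep.start, "end": pep.end,
                "modifications": ";".join(f"{n}@{s}" for n, s in pep.modifications),
                "missed_cleavages": pep.missed_cleavages,
                "theoretical_mass": pep.neutral_mass,
                "observed_mass": m.observed_neutral_mass,
                "deviation_ppm": m.relative_deviation * 1e6,
            })
        report.identifications = pd.DataFrame(id_rows)
        report.stage_counts["database_peptides"] = len(database)
        report.stage_counts["identified_features"] = (
            report.identifications["feature_id"].nunique() if id_rows else 0)
    else:
        logger.warning("no protein sequences supplied; identification skipped")
    return report
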