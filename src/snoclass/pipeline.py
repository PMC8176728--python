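"""End-to-end orchestration: filter -> CV -> threshold -> classify -> correlate -> associate.

``run_pipeline`` executes the stages on the input tables named in an
:class:`AnalysisConfig`, writes every stage output as TSV plus a JSON
summary report, and logs each exclusion decision with counts.
``reproduce_from_supplementary`` re-runs the classification and correlation
stages on a published per-gene supplementary table (with a user-provided
column map) and compares the recomputed headline counts with the published
reference values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, assoc, correlation, data
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

#: Published headline numbers of the seven-tissue human snoRNA atlas that
#: the reproduction mode compares against.
REFERENCE_COUNTS = {
    "expressed_snornas": 475,
    "uniformly_expressed": 390,
    "tissue_enriched": 85,
    "cv_threshold": 125.0,
    "pct_positively_correlated": 60.0,
    "pct_non_or_anticorrelated": 40.0,
}

STAGES = ("classify", "correlate", "associate")


@dataclass
class AnalysisConfig:
    """All tunable constants of a pipeline run, with their canonical defaults."""

    abundance: str = ""
    samples: str = ""
    annotation: str = ""
    outdir: str = "results"
    expression_threshold_tpm: float = 1.0
    exclude_name_prefixes: tuple[str, ...] = ("SCARNA",)
    ddof: int = 1
    kde_bandwidth: str | float = "scott"
    kde_grid_points: int = 1024
    cv_threshold: float | None = None   # override the KDE-tangent threshold
    correlation_level: str = "samples"
    correlation_log2: bool = False
    correlation_cutoffs: tuple[float, float] = (-0.25, 0.25)
    alpha: float = 0.05
    joint_pair: tuple[str, str] = ("breast", "ovary")
    joint_fold: float = 2.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.expression_threshold_tpm <= 0:
            raise ConfigError("expression_threshold_tpm must be positive")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.joint_fold <= 0 or self.pseudocount <= 0:
            raise ConfigError("joint_fold and pseudocount must be positive")
        lo, hi = self.correlation_cutoffs
        if lo >= hi:
            raise ConfigError("correlation cut-offs must be increasing")
        if abs(lo + hi) > 1e-12:
            log.warning("stage=config action=asymmetric_cutoffs lo=%s hi=%s",
                        lo, hi)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("exclude_name_prefixes", "correlation_cutoffs", "joint_pair"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("exclude_name_prefixes", "correlation_cutoffs", "joint_pair"):
            if key in d:
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        loaded = yaml.safe_load(Path(path).read_text())
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(loaded)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_pipeline(config: AnalysisConfig,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the pipeline stages and return the summary report.

    ``stages`` is a subset of ``("classify", "correlate", "associate")``;
    later stages imply the earlier ones.  All stage outputs are written
    under ``config.outdir`` and the report is saved as ``report.json``.
    """
    bad = set(stages) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}")
    want = {s: (s in stages
                or any(STAGES.index(t) > STAGES.index(s) for t in stages))
            for s in STAGES}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}

    try:
        matrix = data.read_abundance_table(config.abundance, config.samples)
        annotation = data.read_annotation(config.annotation)
    except (OSError, DataError) as exc:
        raise DataError(f"stage=load: {exc}") from exc
    report["n_genes_loaded"] = len(matrix.gene_ids)

    filtered, filter_counts = data.filter_expressed(
        matrix, annotation, config.expression_threshold_tpm,
        config.exclude_name_prefixes)
    report["filter"] = filter_counts
    filtered.values.rename_axis("gene_id").to_csv(
        outdir / "filtered_matrix.tsv", sep="\t")

    profile = data.tissue_means(filtered)
    profile.values.rename_axis("gene_id").to_csv(
        outdir / "tissue_profile.tsv", sep="\t")
    breakdown = data.biotype_abundance_breakdown(filtered, annotation)
    breakdown.to_csv(outdir / "biotype_breakdown.tsv", sep="\t", index=False)
    report["biotype_counts"] = (
        annotation.loc[annotation.index.intersection(filtered.values.index),
                       "biotype_group"].value_counts().to_dict())

    # classification operates on the snoRNA subset
    sno_ids = [g for g in filtered.gene_ids
               if g in annotation.index
               and annotation.at[g, "biotype_group"] == "snoRNA"]
    report["n_expressed_snornas"] = len(sno_ids)
    sno_profile = data.TissueProfile(profile.values.loc[sno_ids])
    cv_table = abundance.compute_cv(sno_profile, ddof=config.ddof)

    if config.cv_threshold is not None:
        threshold = float(config.cv_threshold)
        report["threshold"] = {"threshold": threshold, "source": "config"}
    else:
        curve = abundance.estimate_density(
            cv_table["cv"].to_numpy(), bandwidth_rule=config.kde_bandwidth,
            grid_points=config.kde_grid_points)
        tres = abundance.steepest_descent_threshold(curve)
        threshold = tres.threshold
        report["threshold"] = {
            "threshold": threshold,
            "tangent_point_x": tres.tangent_point_x,
            "density_at_point": tres.density_at_point,
            "derivative_at_point": tres.derivative_at_point,
            "bandwidth": curve.bandwidth,
            "grid_points": config.kde_grid_points,
            "source": "kde-tangent",
        }

    assignments = abundance.classify_abundance(cv_table, threshold)
    assignments = abundance.assign_tissue_enrichment(
        sno_profile, assignments, config.joint_pair, config.joint_fold)
    out = assignments.copy()
    out["enriched_tissues"] = [";".join(t) for t in out["enriched_tissues"]]
    out.rename_axis("gene_id").to_csv(outdir / "assignments.tsv", sep="\t")
    n_ue = int((assignments["abundance_class"] == "UE").sum())
    n_te = int((assignments["abundance_class"] == "TE").sum())
    report["abundance_classes"] = {"UE": n_ue, "TE": n_te}
    tally: dict[str, int] = {}
    for ts in assignments.loc[assignments["abundance_class"] == "TE",
                              "enriched_tissues"]:
        for t in ts:
            tally[t] = tally.get(t, 0) + 1
    report["enrichment_tissue_tally"] = dict(sorted(tally.items()))
    (outdir / "threshold.json").write_text(
        json.dumps(_jsonable(report["threshold"]), indent=2, sort_keys=True))

    correlations = pd.DataFrame()
    ratios = pd.DataFrame()
    if want["correlate"]:
        pairs = correlation.pair_snorna_host(annotation.loc[sno_ids])
        records = correlation.correlate_pairs(
            pairs, filtered, level=config.correlation_level,
            log2=config.correlation_log2, pseudocount=config.pseudocount)
        correlations = correlation.finalize_correlations(
            records, cutoffs=config.correlation_cutoffs, alpha=config.alpha)
        correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        ratios = correlation.abundance_ratio(pairs, profile,
                                             pseudocount=config.pseudocount)
        ratios.to_csv(outdir / "ratios.tsv", sep="\t", index=False)
        counts = correlations["correlation_class"].value_counts().to_dict()
        total = max(len(correlations), 1)
        report["correlation_classes"] = {
            "counts": counts,
            "percent": {k: 100.0 * v / total for k, v in sorted(counts.items())},
            "n_pairs": len(correlations),
            "n_significant": int(correlations["significant"].sum())
            if len(correlations) else 0,
        }

    if want["associate"]:
        battery = assoc.class_association_battery(
            assignments, correlations, annotation, ratios)
        assoc.battery_to_frame(battery).to_csv(
            outdir / "associations.tsv", sep="\t", index=False)
        report["associations"] = [{
            "test": r.test, "grouping": r.grouping, "statistic": r.statistic,
            "p": r.p, "stars": r.stars, "n": r.n, "status": r.status,
        } for r in battery]

    assert report["abundance_classes"]["UE"] + report["abundance_classes"]["TE"] \
        == report["n_expressed_snornas"]
    (outdir / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report


def reproduce_from_supplementary(
    s5_path,
    column_map: dict,
    outdir="results_reproduce",
    config: AnalysisConfig | None = None,
) -> dict:
    """Re-run classification (and correlation when possible) on a published
    per-gene supplementary table, and compare with the reference counts.

    ``column_map`` adapts the table's schema::

        gene_id: <column>                       # required
        abundance_columns: {<column>: <tissue>} # required, per-sample TPM
        gene_name: <column>                     # optional
        host_gene_id: <column>                  # optional; enables pairing
        host_abundance_columns: {<column>: <tissue>}  # optional; enables
                                                      # the correlation stage

    Returns a side-by-side comparison dict and writes it as JSON.
    """
    missing = [k for k in ("gene_id", "abundance_columns")
               if k not in column_map]
    if missing:
        raise ConfigError(f"column map is missing required fields: {missing}")
    cfg = config or AnalysisConfig()
    table = pd.read_csv(s5_path, sep=None, engine="python")
    absent = [c for c in [column_map["gene_id"],
                          *column_map["abundance_columns"]]
              if c not in table.columns]
    if absent:
        raise ConfigError(f"columns absent from supplementary table: {absent}")

    table = table.set_index(column_map["gene_id"])
    ab_cols = column_map["abundance_columns"]
    values = table[list(ab_cols)].astype(float)
    sample_to_tissue = pd.Series({c: t for c, t in ab_cols.items()},
                                 name="tissue")
    matrix = data.AbundanceMatrix(values.dropna(axis=0), sample_to_tissue)

    profile = data.tissue_means(matrix)
    cv_table = abundance.compute_cv(profile, ddof=cfg.ddof)
    curve = abundance.estimate_density(
        cv_table["cv"].to_numpy(), bandwidth_rule=cfg.kde_bandwidth,
        grid_points=cfg.kde_grid_points)
    threshold = abundance.steepest_descent_threshold(curve).threshold
    assignments = abundance.classify_abundance(cv_table, threshold)

    recomputed = {
        "expressed_snornas": len(assignments),
        "uniformly_expressed": int((assignments["abundance_class"] == "UE").sum()),
        "tissue_enriched": int((assignments["abundance_class"] == "TE").sum()),
        "cv_threshold": float(threshold),
    }
    status = {"correlation_stage": "skipped: no host columns mapped"}
    if "host_gene_id" in column_map and "host_abundance_columns" in column_map:
        host_cols = column_map["host_abundance_columns"]
        sno_log = np.log2(values.to_numpy(dtype=float) + cfg.pseudocount) \
            if cfg.correlation_log2 else values.to_numpy(dtype=float)
        host_vals = table[list(host_cols)].astype(float).to_numpy()
        if cfg.correlation_log2:
            host_vals = np.log2(host_vals + cfg.pseudocount)
        rs, ps = [], []
        from scipy.stats import pearsonr
        for i in range(len(table)):
            x, y = sno_log[i], host_vals[i]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
                r, p = pearsonr(x[ok], y[ok])
                rs.append(r)
                ps.append(p)
        if rs:
            classes = [correlation.classify_correlation(r, cfg.correlation_cutoffs)
                       for r in rs]
            n = len(classes)
            pos = classes.count("positive")
            recomputed["pct_positively_correlated"] = 100.0 * pos / n
            recomputed["pct_non_or_anticorrelated"] = 100.0 * (n - pos) / n
            status["correlation_stage"] = "ok"

    comparison = {
        key: {"reference": ref, "recomputed": recomputed.get(key)}
        for key, ref in REFERENCE_COUNTS.items()
    }
    result = {"comparison": comparison, "status": status,
              "n_genes": len(table)}
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "reproduction.json").write_text(
        json.dumps(_jsonable(result), indent=2, sort_keys=True))
    return result
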