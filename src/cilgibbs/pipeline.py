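"""End-to-end orchestration: images or patterns -> inhibition metrics ->
cohort clustering -> survival association -> differential expression.

A run is described by a single config mapping (YAML on disk); every
stage records its parameters, seed and output checksums in a manifest so
any stage can be re-executed from the previous stage's serialised
output.  Stage dependencies form a fixed DAG: metrics need patterns (or
a pre-computed metrics table), clustering needs metrics, association
needs clustering, and differential expression needs the association's
LH-CIL / H-CIL split (or an explicit group assignment).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as cl
from . import de as de_mod
from . import survival as sv
from .geometry import PointPattern
from .spatial import estimate_K, l_metric
from .synthetic import CohortSpec, CountsSpec, gen_cohort, gen_counts

logger = logging.getLogger("cilgibbs")

__all__ = ["RunConfig", "run_pipeline", "compute_inhibition_metrics"]

SCHEMA_VERSION = 1
STAGE_ORDER = ["simulate", "metrics", "cluster", "associate", "de"]
STAGE_DEPS = {
    "metrics": ["simulate"],      # or external patterns/metrics input
    "cluster": ["metrics"],
    "associate": ["cluster"],
    "de": ["associate"],
}


def compute_inhibition_metrics(patterns: dict[str, PointPattern],
                               r_grid=None, geyer_r_candidates=None,
                               sat_candidates=(1, 2, 3),
                               correction: str = "isotropic",
                               min_points: int = 10) -> pd.DataFrame:
    """Per-patient inhibition metric M(r) = (L_r, G_r).

    G_r is the fitted Geyer interaction radius, profiled over the
    pattern's nearest-neighbour distance quantiles (interaction radii
    are of nearest-neighbour order; at larger radii the saturation
    statistic is nearly constant and the fit ill-conditioned).  L_r is
    the radius maximising |L(r) - r|, searched by default over the SAME
    radius range as the Geyer candidates: the two coordinates are
    compared and averaged downstream, so both optima must refer to the
    same scale.  Patients whose pattern has fewer than ``min_points``
    points are returned with NaN metrics (unassignable).
    """
    from .geyer import GeyerModel

    rows = []
    for pid, pat in patterns.items():
        row = {"patient_id": pid, "n_cells": pat.n,
               "L_r": np.nan, "G_r": np.nan,
               "gamma": np.nan, "hard_core": np.nan}
        if pat.n >= max(min_points, 2):
            model = GeyerModel(pat, geyer_r_candidates, sat_candidates,
                               min_points=min_points)
            fit = model.fit()
            if r_grid is None:
                grid = np.linspace(0.0, model.r_candidates.max(), 256)
            else:
                grid = r_grid
            est = estimate_K(pat, grid, correction)
            row["L_r"], row["L_dev"] = l_metric(est)
            row["G_r"] = fit.interaction_radius
            row["gamma"] = fit.gamma
            row["hard_core"] = fit.hard_core
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Validated pipeline configuration (schema v1)."""

    output_dir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        s: True for s in STAGE_ORDER})
    cohort: dict = field(default_factory=dict)      # CohortSpec overrides
    counts: dict = field(default_factory=dict)      # CountsSpec overrides
    metrics_csv: str | None = None                  # skip simulate+metrics
    span: float = 0.3
    band_multiplier: float = 4.0
    fdr: float = 0.001
    lfc: float = 6.0
    k_range: tuple = (2, 8)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema {version}")
        return cls(**raw)

    def validate(self) -> None:
        enabled = [s for s in STAGE_ORDER if self.stages.get(s)]
        for s in enabled:
            for dep in STAGE_DEPS.get(s, []):
                dep_ok = self.stages.get(dep) or (
                    dep in ("simulate", "metrics")
                    and self.metrics_csv is not None)
                if not dep_ok:
                    raise ValueError(
                        f"stage {s!r} enabled but dependency {dep!r} is "
                        "disabled and no substitute input is configured")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return the manifest dict.

    The manifest (also written to <output_dir>/manifest.json) records the
    config, per-stage timing, seeds and output-file checksums; re-running
    with the same config reproduces every output bit for bit.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # per-stage seeds are derived independently of which stages run, so a
    # run resumed from a serialised intermediate reproduces the full run
    children = np.random.SeedSequence(config.seed).spawn(len(STAGE_ORDER))
    stage_seed = {s: int(c.generate_state(1)[0] % (2 ** 31))
                  for s, c in zip(STAGE_ORDER, children)}
    manifest = {"schema_version": SCHEMA_VERSION,
                "config": {**config.__dict__,
                           "stages": dict(config.stages),
                           "k_range": list(config.k_range)},
                "stages": {}}
    state: dict = {}

    def record(stage, t0, files, **extra):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {str(f): _sha256(Path(f)) for f in files},
            **extra,
        }

    enabled = [s for s in STAGE_ORDER if config.stages.get(s)]

    try:
        if "simulate" in enabled and config.metrics_csv is None:
            t0 = time.time()
            spec = CohortSpec(**{"seed": stage_seed["simulate"],
                                 **config.cohort})
            patterns, table = gen_cohort(spec)
            state["patterns"], state["cohort"] = patterns, table
            f = out / "cohort.csv"
            table.to_csv(f, index=False)
            record("simulate", t0, [f], n_patients=len(table))
            logger.info("simulate: %d patients", len(table))

        if "metrics" in enabled or config.metrics_csv is not None:
            t0 = time.time()
            if config.metrics_csv is not None:
                metrics = pd.read_csv(config.metrics_csv)
                files = []
            else:
                metrics = compute_inhibition_metrics(state["patterns"])
                metrics = metrics.merge(state["cohort"], on="patient_id")
                f = out / "metrics.csv"
                metrics.to_csv(f, index=False)
                # downstream stages consume the serialised table so a
                # resumed run sees bit-identical inputs
                metrics = pd.read_csv(f)
                files = [f]
            state["metrics"] = metrics
            record("metrics", t0, files, n_rows=len(metrics))
            logger.info("metrics: %d rows", len(metrics))

        if "cluster" in enabled:
            t0 = time.time()
            m = state["metrics"].dropna(subset=["L_r", "G_r"]).copy()
            m = cl.zscore_metrics(m)
            X = m[["z_G_r", "z_L_r"]].to_numpy()
            seed = stage_seed["cluster"]
            lo, hi = config.k_range
            if len(m) >= 2 * hi:
                k_star, votes = cl.optimal_k(X, range(lo, hi + 1), seed=seed)
            else:
                k_star, votes = 2, {}
            res = cl.kmeans_cluster(X, 2, seed=seed)
            if "gamma" in m.columns and m["gamma"].notna().any():
                res.group_of_cluster = cl.name_groups_by_interaction(
                    res.labels, m["gamma"].to_numpy())
            m["group"] = res.group_labels
            state["clustered"], state["cluster_result"] = m, res
            f = out / "clustered.csv"
            m.to_csv(f, index=False)
            fv = out / "votes.json"
            fv.write_text(json.dumps({"optimal_k": k_star, "votes": votes}))
            record("cluster", t0, [f, fv], optimal_k=k_star,
                   group_sizes=m["group"].value_counts().to_dict())
            logger.info("cluster: k*=%d sizes=%s", k_star,
                        m["group"].value_counts().to_dict())

        if "associate" in enabled:
            t0 = time.time()
            m, res = state["clustered"], state["cluster_result"]
            gibbs_cluster = next(c for c, g in res.group_of_cluster.items()
                                 if g == cl.GROUP_GIBBS)
            centroid = res.centroids[gibbs_cluster]
            gibbs = m[m["group"] == cl.GROUP_GIBBS]
            if len(gibbs) >= 10:
                assoc = sv.associate_group(
                    gibbs, centroid, span=config.span,
                    multiplier=config.band_multiplier,
                    seed=stage_seed["associate"])
                report = {
                    "fisher_p": assoc["band"].p_value,
                    "table": assoc["band"].table.tolist(),
                    "establishment_index": assoc["establishment_index"],
                    "establishment_days": assoc["establishment_days"],
                }
            else:
                # too few inhibited patients for a meaningful smooth
                assoc = {"cil_subgroup": None}
                report = {"fisher_p": None, "table": None,
                          "establishment_index": None,
                          "establishment_days": None,
                          "skipped": f"Gibbs group has {len(gibbs)} "
                                     "patients (< 10)"}
            _, stat, p, reliable = sv.km_logrank(m)
            report["logrank_stat"], report["logrank_p"] = stat, p
            report["logrank_reliable"] = reliable
            f = out / "association.json"
            f.write_text(json.dumps(report, indent=2))
            files = [f]
            if assoc["cil_subgroup"] is not None:
                sub = assoc["sorted_records"][["patient_id"]].copy()
                sub["cil_subgroup"] = assoc["cil_subgroup"].to_numpy()
                fs = out / "cil_subgroups.csv"
                sub.to_csv(fs, index=False)
                files.append(fs)
                state["cil_subgroups"] = sub
            state["association"] = report
            record("associate", t0, files, **{
                k: v for k, v in report.items() if not isinstance(v, list)})
            logger.info("associate: fisher_p=%s logrank_p=%.4g",
                        report["fisher_p"], report["logrank_p"])

        if "de" in enabled:
            t0 = time.time()
            spec = CountsSpec(**{"seed": stage_seed["de"],
                                 **config.counts})
            counts, groups, truth = gen_counts(spec)
            result = de_mod.fit_nb_glm_lrt(counts, groups)
            sig_genes = de_mod.apply_cutoffs(result, config.fdr, config.lfc)
            f = out / "de_table.tsv"
            result.table.to_csv(f, sep="\t")
            f2 = out / "de_genes.txt"
            f2.write_text("\n".join(sig_genes) + "\n")
            state["de"] = result
            record("de", t0, [f, f2], n_significant=len(sig_genes),
                   n_planted=len(truth))
            logger.info("de: %d significant genes", len(sig_genes))
    except KeyError as e:  # pragma: no cover - guarded by validate()
        raise RuntimeError(f"stage input missing: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
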