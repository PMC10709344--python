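"""End-to-end orchestration: simulate → well metrics → single-organoid →
heterogeneity map → pseudotime → clinical.

A single :class:`RunConfig` governs every stage; rerunning the same config
reproduces identical outputs (the manifest records a config hash, the
seeds and package versions). Stages write plain CSV/YAML/JSON into the run
directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import correlate_with_pfs, signature_concordance
from .errors import ConfigError
from .heterogeneity import map_heterogeneity
from .io import read_layout, read_measurements, write_layout, write_measurements
from .pseudotime import density_along_path, infer_trajectory
from .simulate import default_scenarios, simulate_plate
from .singleorg import ResponseThresholds, class_fractions, invasion_metrics, organoid_states
from .wellmetrics import classify_signature, dose_response_table, plate_well_metrics

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "select_terminal_clusters", "synthetic_cohort"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run, with screen-convention defaults."""

    out_dir: str = "orgscreen_run"
    seed: int = 0
    scenario: str = "heterogeneous"  # used when no measurement files are given
    measurements_path: str | None = None
    layout_path: str | None = None
    clinical_path: str | None = None
    thresholds: ResponseThresholds = field(default_factory=ResponseThresholds)
    death_threshold_pct: float = 40.0
    ndr_cytotoxic: float = -0.5
    n_perm: int = 1000
    knn_k: int = 1000
    louvain_resolution: float = 1.0
    endpoint_h: float | None = None
    cohort_patients: int = 7  # synthetic clinical cohort when none supplied
    organoids_per_well: float | None = None  # override the scenario's seeding density
    n_replicates: int | None = None  # override the scenario's technical replicates

    def validate(self) -> None:
        self.thresholds.validate()
        if self.n_perm < 1 or self.knn_k < 1 or self.cohort_patients < 3:
            raise ConfigError("n_perm, knn_k must be >= 1 and cohort_patients >= 3")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = ResponseThresholds(**thr)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")  # where outputs land does not change what they are
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def select_terminal_clusters(profiles: pd.DataFrame, baseline_cluster: int) -> dict[str, int]:
    """Pick the resistant / sensitive / invasive terminal clusters.

    From the mean rank-normalized cluster profiles: *sensitive* maximizes
    fraction affected, *invasive* maximizes invasive fraction, *resistant*
    minimizes fraction affected — all excluding the baseline (root)
    cluster, resolving collisions by the next-best cluster.
    """
    prof = profiles[profiles["cluster"] != baseline_cluster].set_index("cluster")
    if prof.empty:
        raise ConfigError("only the baseline cluster exists; no terminals to pick")
    chosen: dict[str, int] = {}

    def pick(series: pd.Series, reverse: bool) -> int:
        order = series.sort_values(ascending=not reverse).index
        for c in order:
            if c not in chosen.values():
                return int(c)
        return int(order[0])

    chosen["sensitive"] = pick(prof["fa"], reverse=True)
    if "inv_fraction" in prof.columns:  # absent when invasion was constant (e.g. all zero)
        inv_score = prof["inv_fraction"]
        if "inv_area" in prof.columns:  # invasive state = high annulus area AND fraction
            inv_score = (inv_score + prof["inv_area"]) / 2
        chosen["invasive"] = pick(inv_score, reverse=True)
    chosen["resistant"] = pick(prof["fa"], reverse=False)
    return chosen


def synthetic_cohort(
    seed: int, n_patients: int = 7, organoids_per_well: int = 80,
    thresholds: ResponseThresholds = ResponseThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a small multi-patient cohort for the clinical stage.

    Each patient gets a different planted resistant-subclone fraction; the
    matching synthetic clinical table assigns PFS decreasing in that
    fraction (with seeded jitter) so that organoid-derived readouts carry a
    recoverable clinical signal. Returns (per-patient class fractions at
    the saturating dose, clinical table).
    """
    rng = np.random.default_rng(seed)
    rhos = np.linspace(0.08, 0.75, n_patients)
    frac_rows, clin_rows = [], []
    base = default_scenarios(seed)["heterogeneous"]
    for i, rho in enumerate(rhos):
        patient = f"SIM{i + 1:03d}"
        clones = (
            replace(base.clones[0], fraction=round(1 - rho, 6)),
            replace(base.clones[1], fraction=round(rho, 6)),
        )
        cfg = replace(
            base, clones=clones, seed=int(rng.integers(2**31)),
            organoids_per_well=float(organoids_per_well),
            regimens={"gem-pac": [{"gemcitabine": 400.0, "paclitaxel": 80.0}]},
            patient_id=patient, plate_id=f"plate-{patient}",
        )
        m, layout, _ = simulate_plate(cfg)
        states = organoid_states(m, layout, thresholds)
        endpoint = states["time_h"].max()
        trt = states[(states["role"] == "treatment") & (states["time_h"] == endpoint)]
        fr = class_fractions(trt.assign(patient_id=patient), ["patient_id"])
        frac_rows.append(fr)
        pfs = float(np.clip(14.0 * (1 - rho) + rng.normal(0, 0.3), 1.0, None))
        clin_rows.append({
            "patient_id": patient, "pfs_months": round(pfs, 2),
            "censored": False,
            "response_category": "good" if rho < 0.3 else ("mixed" if rho < 0.55 else "bad"),
            "regimen": "gem-pac",
        })
    return pd.concat(frac_rows, ignore_index=True), pd.DataFrame(clin_rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage, write its outputs under ``cfg.out_dir``, return the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "orgscreen_version": __version__,
        "stages": {},
    }

    # stage 1: obtain data (simulate or load)
    if cfg.measurements_path and cfg.layout_path:
        measurements = read_measurements(cfg.measurements_path)
        layout = read_layout(cfg.layout_path)
    else:
        scenarios = default_scenarios(cfg.seed)
        if cfg.scenario not in scenarios:
            raise ConfigError(f"unknown scenario {cfg.scenario!r}; options: {sorted(scenarios)}")
        sim_cfg = scenarios[cfg.scenario]
        if cfg.organoids_per_well is not None:
            sim_cfg = replace(sim_cfg, organoids_per_well=float(cfg.organoids_per_well))
        if cfg.n_replicates is not None:
            sim_cfg = replace(sim_cfg, n_replicates=int(cfg.n_replicates))
        measurements, layout, truth = simulate_plate(sim_cfg)
        truth.organoids.to_csv(out / "truth_organoids.csv", index=False)
        truth.wells.to_csv(out / "truth_wells.csv", index=False)
    write_measurements(measurements, out / "measurements.csv")
    write_layout(layout, out / "layout.yaml")
    manifest["stages"]["simulate"] = {"n_rows": len(measurements), "n_wells": len(layout.wells)}

    # stage 2: well metrics
    wm = plate_well_metrics(measurements, layout)
    wm.to_csv(out / "wellmetrics.csv", index=False)
    dr = dose_response_table(wm, endpoint_h=cfg.endpoint_h)
    dr.to_csv(out / "doseresponse.csv", index=False)
    endpoint = dr["endpoint_h"].iloc[0]
    sig_rows = [
        {"regimen": reg, **dataclasses.asdict(classify_signature(
            grp["ndr"].iloc[-1], grp["cell_death_pct"].iloc[-1],
            death_threshold=cfg.death_threshold_pct, ndr_cytotoxic=cfg.ndr_cytotoxic,
        ))}
        for reg, grp in dr.groupby("regimen")
    ]
    pd.DataFrame(sig_rows).to_csv(out / "signatures.csv", index=False)
    manifest["stages"]["wellmetrics"] = {"endpoint_h": float(endpoint), "n_wells": wm["well"].nunique()}

    # stage 3: single-organoid states
    states = organoid_states(measurements, layout, cfg.thresholds)
    states.to_csv(out / "states.csv", index=False)
    fr = class_fractions(states, ["well", "time_h"])
    fr.to_csv(out / "fractions.csv", index=False)
    inv = invasion_metrics(states, ["regimen"])
    inv.to_csv(out / "invasion.csv", index=False)
    manifest["stages"]["singleorg"] = {"n_states": len(states)}

    # stage 4: heterogeneity map
    model = map_heterogeneity(
        states, seed=cfg.seed, n_perm=cfg.n_perm, knn_k=cfg.knn_k,
        resolution=cfg.louvain_resolution,
    )
    emb = model.feature_matrix.meta.copy()
    emb[["tsne1", "tsne2"]] = model.coords
    emb["cluster"] = model.labels
    emb.to_csv(out / "embedding.csv", index=False)
    model.profiles.to_csv(out / "cluster_profiles.csv", index=False)
    model.enrichment.to_csv(out / "cluster_enrichment.csv", index=False)
    manifest["stages"]["map"] = {
        "n_obs": len(model.labels),
        "n_clusters": int(model.labels.max()),
        "n_retained_pcs": int(model.pc_table["retained"].sum()),
        "perplexity": model.perplexity,
        "baseline_cluster": model.baseline_cluster,
    }

    # stage 5: pseudotime
    terminals = select_terminal_clusters(model.profiles, model.baseline_cluster)
    traj = infer_trajectory(
        model.labels, model.coords, root=model.baseline_cluster,
        terminals=tuple(sorted(set(terminals.values()))),
    )
    pt = traj.pseudotime.copy()
    pt.insert(0, "cluster", model.labels)
    pt.to_csv(out / "pseudotime.csv", index=False)
    inv_leaf = terminals.get("invasive")
    col = f"path_to_{inv_leaf}"
    if inv_leaf is not None and col in traj.pseudotime:
        dens = density_along_path(
            traj.pseudotime[col], model.feature_matrix.meta["regimen"].to_numpy()
        )
        dens.to_csv(out / "invasive_path_density.csv", index=False)
    manifest["stages"]["pseudotime"] = {
        "root": traj.root, "terminals": terminals,
        "mst_edges": [list(e) for e in traj.edges],
    }

    # stage 6: clinical correlation (supplied cohort, or a synthetic one)
    if cfg.clinical_path:
        from .io import read_clinical

        clin = read_clinical(cfg.clinical_path)
        endpoint_states = states[states["time_h"] == states["time_h"].max()]
        trt = endpoint_states[endpoint_states["role"] == "treatment"]
        fractions = class_fractions(trt.assign(patient_id=layout.to_frame()["patient_id"].iloc[0]),
                                    ["patient_id"])
    else:
        fractions, clin = synthetic_cohort(
            cfg.seed, n_patients=cfg.cohort_patients, thresholds=cfg.thresholds
        )
        clin.to_csv(out / "clinical_synthetic.csv", index=False)
    corr = correlate_with_pfs(fractions, clin)
    corr.to_csv(out / "pfs_correlations.csv", index=False)
    manifest["stages"]["clinical"] = {
        "n_patients": int(corr["n"].iloc[0]),
        "rho_pct_sensitive": float(corr.loc[corr["readout"] == "pct_sensitive", "rho"].iloc[0]),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
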