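"""End-to-end orchestration: simulate -> preprocess -> metrics -> LME -> summaries.

A single PipelineConfig drives the whole analysis: a synthetic longitudinal
cohort is generated on an icosphere, each session is cleaned and branched
into the three processing states the metrics require, the eight metric maps
are computed per session, long-format tables are assembled and decomposed
into variance components per vertex and for the global mean, and the ICC
maps are summarized per network label.  Everything is deterministic under
the master seed; the run manifest records config hash, output checksums and
QC counters so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .connectome import correlation_graph, degree_centrality, \
    density_threshold, eigenvector_centrality
from .core import MetricMap, SessionTimeSeries
from .local_metrics import amplitude_metrics, reho
from .mesh import SurfaceMesh, build_icosphere
from .meso_metrics import dual_regression, interplay_matrix, seed_from_atlas, sfc
from .preprocess import bandpass, build_nuisance_design, despike, \
    discard_initial, regress_nuisance, scale_global_mean, smooth_session, \
    znormalize
from .synthetic import Cohort, CohortConfig, NetworkAtlas, assign_networks, \
    simulate_cohort
from .variance import VarianceDecomposition, fit_metric_models, \
    summarize_by_labels

logger = logging.getLogger(__name__)

ALL_METRICS = ("ALFF", "fALFF", "ReHo1", "ReHo2", "SFC", "DR", "DCw", "ECw")
STAGES = ("simulate", "preprocess", "metrics", "model", "summarize")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults follow the study's parameters."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    subdivisions: int = 2
    n_networks: int = 7
    # preprocessing
    n_drop: int = 5
    spike_z: float = 5.0
    global_target: float = 10_000.0
    band: Tuple[float, float] = (0.01, 0.1)
    fwhm_mm: float = 6.0
    edge_length_mm: float = 4.0
    # metrics
    metrics: Tuple[str, ...] = ALL_METRICS
    seed_label: int = 7            # synthetic default-network patch for SFC
    dr_network: Optional[int] = None   # which DR map feeds the LME (default: seed_label)
    density: float = 0.05
    # models
    model_levels: Tuple[str, ...] = ("global", "vertex")
    summary_threshold: float = 0.4
    fit_interplay: bool = False

    def validate(self) -> None:
        self.cohort.validate()
        unknown = set(self.metrics) - set(ALL_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if self.n_drop < 0 or self.n_drop >= self.cohort.t_raw:
            raise ValueError("n_drop out of range")
        if self.fwhm_mm < 0 or self.edge_length_mm <= 0:
            raise ValueError("invalid smoothing parameters")
        if not (1 <= self.seed_label <= self.n_networks):
            raise ValueError("seed_label outside the atlas")
        for lvl in self.model_levels:
            if lvl not in ("global", "vertex"):
                raise ValueError(f"unknown model level {lvl!r}")


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    cohort = CohortConfig(**d.pop("cohort", {}))
    for key in ("band",):
        if key in d:
            d[key] = tuple(d[key])
    if "metrics" in d:
        d["metrics"] = tuple(d["metrics"])
    if "model_levels" in d:
        d["model_levels"] = tuple(d["model_levels"])
    return PipelineConfig(cohort=cohort, **d)


# ---------------------------------------------------------------------------
# per-session preprocessing and metrics
# ---------------------------------------------------------------------------

def preprocess_session(ts: SessionTimeSeries, mesh: SurfaceMesh,
                       cfg: PipelineConfig,
                       need: Sequence[str] = ("cleaned", "bandpassed",
                                              "znormalized", "smoothed"),
                       ) -> Dict[str, SessionTimeSeries]:
    """Clean one session and branch into the requested processing states."""
    ts = discard_initial(ts, cfg.n_drop)
    ts, spike_mask = despike(ts, cfg.spike_z)
    ts = scale_global_mean(ts, cfg.global_target)
    design = build_nuisance_design(ts)
    cleaned = regress_nuisance(ts, design)
    out: Dict[str, SessionTimeSeries] = {"cleaned": cleaned}
    out["n_spikes"] = int(spike_mask.sum())
    if "bandpassed" in need or "znormalized" in need:
        bp = bandpass(cleaned, *cfg.band)
        out["bandpassed"] = bp
        if "znormalized" in need:
            out["znormalized"] = znormalize(bp)
    if "smoothed" in need:
        out["smoothed"] = smooth_session(cleaned, mesh, cfg.fwhm_mm,
                                         cfg.edge_length_mm)
    return out


def _states_needed(metrics: Sequence[str]) -> Tuple[str, ...]:
    need = {"cleaned"}
    if {"ReHo1", "ReHo2", "DCw", "ECw", "SFC"} & set(metrics):
        need.add("bandpassed")
    if "SFC" in metrics:
        need.add("znormalized")
    if {"ALFF", "fALFF"} & set(metrics):
        need.add("smoothed")
    return tuple(need)


def compute_session_metrics(states: Dict[str, SessionTimeSeries],
                            mesh: SurfaceMesh, atlas: NetworkAtlas,
                            cfg: PipelineConfig
                            ) -> Tuple[Dict[str, MetricMap], Optional[np.ndarray]]:
    """All requested metric maps for one session; returns (maps, interplay)."""
    maps: Dict[str, MetricMap] = {}
    interplay = None
    if {"ALFF", "fALFF"} & set(cfg.metrics):
        alff, falff = amplitude_metrics(states["smoothed"], cfg.band)
        if "ALFF" in cfg.metrics:
            maps["ALFF"] = alff
        if "fALFF" in cfg.metrics:
            maps["fALFF"] = falff
    for rings, name in ((1, "ReHo1"), (2, "ReHo2")):
        if name in cfg.metrics:
            maps[name] = reho(states["bandpassed"], mesh, rings)
    if "SFC" in cfg.metrics:
        seed = seed_from_atlas(atlas, cfg.seed_label)
        maps["SFC"] = sfc(states["znormalized"], seed)
    if "DR" in cfg.metrics:
        res = dual_regression(states["cleaned"], atlas.template_maps)
        net = (cfg.dr_network or cfg.seed_label) - 1
        cleaned = states["cleaned"]
        maps["DR"] = MetricMap(values=res.spatial_maps[:, net], metric="DR",
                               subject_id=cleaned.subject_id,
                               session_id=cleaned.session_id,
                               meta={"network": net + 1})
        interplay = interplay_matrix(res.time_courses)
    if {"DCw", "ECw"} & set(cfg.metrics):
        g = density_threshold(correlation_graph(states["bandpassed"]),
                              cfg.density,
                              subject_id=states["bandpassed"].subject_id,
                              session_id=states["bandpassed"].session_id)
        if "DCw" in cfg.metrics:
            maps["DCw"] = degree_centrality(g)
        if "ECw" in cfg.metrics:
            maps["ECw"] = eigenvector_centrality(g)
    return maps, interplay


# ---------------------------------------------------------------------------
# long-format tables
# ---------------------------------------------------------------------------

def build_longitudinal_table(values: pd.DataFrame, cohort: Cohort,
                             level: str) -> pd.DataFrame:
    """Assemble the LME input table for one metric.

    ``values`` has one row per (subject, session) and one column per vertex.
    For the global level the target is the metric's cross-vertex mean gM; for
    the vertex level each vertex is a target and gM, mcBBR and the subject's
    per-vertex Jacobian enter as covariates.
    """
    cov = cohort.covariates.set_index(["subject", "session"])
    gm = values.mean(axis=1)
    if level == "global":
        df = cov.copy()
        df["value"] = gm
        df["target"] = "global"
        return df.reset_index()
    subj_index = {s: i for i, s in enumerate(cohort.subject_ids)}
    rows = []
    for (subject, session), _ in values.iterrows():
        base = cov.loc[(subject, session)]
        rows.append(dict(subject=subject, session=session,
                         age=base["age"], sex=base["sex"],
                         meanFD=base["meanFD"], mcBBR=base["mcBBR"],
                         gM=gm.loc[(subject, session)]))
    meta = pd.DataFrame(rows)
    V = values.shape[1]
    n = len(values)
    long = meta.loc[meta.index.repeat(V)].reset_index(drop=True)
    long["target"] = np.tile(np.arange(V), n)
    long["value"] = values.to_numpy().ravel()
    jrows = np.array([subj_index[s] for s in meta["subject"]])
    long["jacobian"] = cohort.jacobian[jrows].ravel()
    return long


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    cohort: Cohort
    metric_values: Dict[str, pd.DataFrame]      # metric -> (sessions x V)
    interplay: Dict[Tuple[str, str], np.ndarray]
    global_fits: Dict[str, VarianceDecomposition]
    vertex_fits: Dict[str, Dict[object, VarianceDecomposition]]
    interplay_fits: Dict[Tuple[int, int], VarianceDecomposition]
    summaries: Dict[str, pd.DataFrame]
    manifest: dict


def fit_interplay_models(interplay: Dict[Tuple[str, str], np.ndarray],
                         cohort: Cohort
                         ) -> Dict[Tuple[int, int], VarianceDecomposition]:
    """Whole-brain LME per network pair on the Fisher-z interplay values."""
    cov = cohort.covariates.set_index(["subject", "session"])
    fits: Dict[Tuple[int, int], VarianceDecomposition] = {}
    keys = list(interplay)
    L = interplay[keys[0]].shape[0]
    for l1 in range(L):
        for l2 in range(l1 + 1, L):
            rows = []
            for (subject, session), M in interplay.items():
                if not np.isfinite(M[l1, l2]):
                    continue
                base = cov.loc[(subject, session)]
                rows.append(dict(subject=subject, session=session,
                                 target=(l1 + 1, l2 + 1),
                                 value=M[l1, l2], age=base["age"],
                                 sex=base["sex"], meanFD=base["meanFD"]))
            table = pd.DataFrame(rows)
            fits[(l1 + 1, l2 + 1)] = fit_metric_models(
                table, "global")[(l1 + 1, l2 + 1)]
    return fits


def _decomposition_frame(fits: Dict[object, VarianceDecomposition]
                         ) -> pd.DataFrame:
    rows = []
    for target, d in fits.items():
        row = dict(target=target, sigma_b2=d.sigma_b2, sigma_w2=d.sigma_w2,
                   icc=d.icc, band=d.band, intra_strength=d.intra_strength,
                   inter_strength=d.inter_strength, z_intercept=d.z_intercept,
                   boundary=d.boundary, n_obs=d.n_obs,
                   n_subjects=d.n_subjects)
        for name, b, se in zip(d.beta_names, d.beta, d.beta_se):
            row[f"beta_{name}"] = b
            row[f"se_{name}"] = se
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig,
                 out_dir: Optional[Path] = None,
                 stages: Sequence[str] = STAGES) -> PipelineResult:
    """Execute the enabled stages in dependency order.

    Later stages imply the earlier ones (the cohort is synthetic and cheap to
    regenerate), so ``stages`` simply truncates the pipeline.  With the same
    config the run is bit-reproducible; the manifest's checksums prove it.
    """
    config.validate()
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    last = max(STAGES.index(s) for s in stages)

    mesh = build_icosphere(config.subdivisions)
    atlas = assign_networks(mesh, config.n_networks, config.cohort.seed + 1)
    cohort = simulate_cohort(mesh, atlas, config.cohort)
    qc = {"n_spikes_interpolated": 0, "n_boundary_fits": 0,
          "n_masked_vertices": 0}

    metric_values: Dict[str, pd.DataFrame] = {}
    interplay: Dict[Tuple[str, str], np.ndarray] = {}
    if last >= STAGES.index("metrics"):
        need = _states_needed(config.metrics)
        per_metric: Dict[str, List[np.ndarray]] = {m: [] for m in config.metrics}
        index = []
        for ts in cohort.sessions:
            states = preprocess_session(ts, mesh, config, need)
            qc["n_spikes_interpolated"] += states.pop("n_spikes")
            maps, ip = compute_session_metrics(states, mesh, atlas, config)
            for m in config.metrics:
                mm = maps[m]
                vals = mm.values.copy()
                if mm.mask is not None:
                    qc["n_masked_vertices"] += int(mm.mask.sum())
                    vals[mm.mask] = np.nan
                per_metric[m].append(vals)
            if ip is not None:
                interplay[(ts.subject_id, ts.session_id)] = ip
            index.append((ts.subject_id, ts.session_id))
        idx = pd.MultiIndex.from_tuples(index, names=["subject", "session"])
        for m in config.metrics:
            metric_values[m] = pd.DataFrame(np.vstack(per_metric[m]),
                                            index=idx)

    global_fits: Dict[str, VarianceDecomposition] = {}
    vertex_fits: Dict[str, Dict[object, VarianceDecomposition]] = {}
    if last >= STAGES.index("model"):
        for m, values in metric_values.items():
            # DR spatial maps have no meaningful global mean (their spatial
            # mean is fixed by the stage-2 regression algebra), so DR gets no
            # global-level model and no gM covariate at the vertex level
            if "global" in config.model_levels and m != "DR":
                table = build_longitudinal_table(values, cohort, "global")
                fit = fit_metric_models(table, "global")["global"]
                global_fits[m] = fit
                qc["n_boundary_fits"] += int(fit.boundary)
            if "vertex" in config.model_levels:
                table = build_longitudinal_table(values, cohort, "vertex")
                table = table.dropna(subset=["value"])
                fits = fit_metric_models(table, "vertex", include_gm=(m != "DR"))
                vertex_fits[m] = fits
                qc["n_boundary_fits"] += sum(d.boundary for d in fits.values())

    interplay_fits: Dict[Tuple[int, int], VarianceDecomposition] = {}
    if (last >= STAGES.index("model") and config.fit_interplay
            and interplay):
        interplay_fits = fit_interplay_models(interplay, cohort)

    summaries: Dict[str, pd.DataFrame] = {}
    if last >= STAGES.index("summarize") and vertex_fits:
        for m, fits in vertex_fits.items():
            icc_map = np.full(mesh.vertex_count, np.nan)
            for target, d in fits.items():
                icc_map[int(target)] = d.icc
            summaries[m] = summarize_by_labels(icc_map, atlas.labels,
                                               config.summary_threshold)

    manifest = _write_outputs(config, cohort, metric_values, interplay,
                              global_fits, vertex_fits, interplay_fits,
                              summaries, qc, out_dir)
    return PipelineResult(cohort=cohort, metric_values=metric_values,
                          interplay=interplay, global_fits=global_fits,
                          vertex_fits=vertex_fits,
                          interplay_fits=interplay_fits,
                          summaries=summaries, manifest=manifest)


# ---------------------------------------------------------------------------
# formats and manifest
# ---------------------------------------------------------------------------

def write_matrix_tsv(path: Path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=np.float64),
               delimiter="\t", fmt="%.12g")


def read_matrix_tsv(path: Path) -> np.ndarray:
    try:
        return np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    except ValueError as e:
        raise ValueError(f"malformed matrix TSV {path}: {e}") from e


def write_edge_list(path: Path, g) -> None:
    """Edge-list TSV (i, j, weight) with a JSON header sidecar."""
    coo = g.weights.tocoo()
    keep = coo.row < coo.col
    df = pd.DataFrame({"i": coo.row[keep], "j": coo.col[keep],
                       "weight": coo.data[keep]})
    df.sort_values(["i", "j"]).to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(json.dumps(
        {"n_vertices": g.n_vertices, "density": g.density,
         "n_edges": g.n_edges}))


def read_edge_list(path: Path):
    from scipy.sparse import csr_matrix
    df = pd.read_csv(path, sep="\t")
    header = json.loads(Path(str(path) + ".json").read_text())
    if (df["i"] == df["j"]).any():
        bad = df.index[df["i"] == df["j"]][0]
        raise ValueError(f"self-loop at line {bad + 2} of {path}")
    V = header["n_vertices"]
    rows = np.concatenate([df["i"], df["j"]])
    cols = np.concatenate([df["j"], df["i"]])
    vals = np.concatenate([df["weight"], df["weight"]])
    from .connectome import ConnectomeGraph
    return ConnectomeGraph(weights=csr_matrix((vals, (rows, cols)),
                                              shape=(V, V)),
                           density=header["density"],
                           n_edges=header["n_edges"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["cohort"]["sigma_b"] = np.asarray(config.cohort.sigma_b).tolist()
    d["cohort"]["sigma_w"] = np.asarray(config.cohort.sigma_w).tolist()
    return d


def _write_outputs(config, cohort, metric_values, interplay, global_fits,
                   vertex_fits, interplay_fits, summaries, qc,
                   out_dir) -> dict:
    cfg_json = json.dumps(_config_dict(config), sort_keys=True)
    manifest = {
        "software_version": __version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "qc": qc,
        "outputs": {},
    }
    if out_dir is None:
        return manifest
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mesh = cohort.mesh
    write_matrix_tsv(out / "mesh_vertices.tsv", mesh.coordinates)
    np.savetxt(out / "mesh_triangles.tsv", mesh.triangles,
               delimiter="\t", fmt="%d")
    np.savetxt(out / "atlas_labels.tsv", cohort.atlas.labels, fmt="%d")
    cohort.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(json.dumps({
        "sigma_b2": cohort.truth.sigma_b2.tolist(),
        "sigma_w2": cohort.truth.sigma_w2.tolist(),
        "icc": cohort.truth.icc.tolist(),
        "covariate_effects": cohort.truth.covariate_effects,
    }))
    for m, values in metric_values.items():
        values.to_csv(out / f"metric_{m}.tsv", sep="\t")
    for m, fit in global_fits.items():
        _decomposition_frame({"global": fit}).to_csv(
            out / f"model_{m}_global.tsv", sep="\t", index=False)
    for m, fits in vertex_fits.items():
        _decomposition_frame(fits).to_csv(
            out / f"model_{m}_vertex.tsv", sep="\t", index=False)
    for m, summ in summaries.items():
        summ.to_csv(out / f"summary_{m}_icc_by_network.tsv", sep="\t",
                    index=False)
    if interplay_fits:
        _decomposition_frame({f"{a}-{b}": d
                              for (a, b), d in interplay_fits.items()}
                             ).to_csv(out / "model_interplay_global.tsv",
                                      sep="\t", index=False)
    if interplay:
        stack = np.stack(list(interplay.values()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # NaN diagonal
            mean_ip = np.nanmean(stack, axis=0)
        write_matrix_tsv(out / "interplay_mean.tsv", mean_ip)
    (out / "config.json").write_text(cfg_json)

    for f in sorted(out.glob("*")):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
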