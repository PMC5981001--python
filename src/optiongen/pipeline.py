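"""End-to-end orchestration: simulate/read -> score -> embed -> analyze -> report.

Each stage reads and writes the plain CSV interfaces, so any stage can be
re-run in isolation; a JSON run manifest records the config snapshot,
seeds, input hashes and produced files.  A single master seed drives every
stochastic choice (cohort generation and MDS restarts).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    compare_correlations,
    correlate,
    motivation_glm,
    paired_compare,
    summarize,
    tradeoff_mixed_model,
)
from .embedding import convex_hull_area, mds_embed
from .io import read_cohort, write_cohort
from .model import Cohort
from .preprocess import resample, smooth_trajectory, validate_path
from .similarity import build_features, distance_matrix, uniqueness_from_matrix
from .simulate import GeneratorConfig, simulate_cohort

__all__ = [
    "DEFAULTS",
    "RunManifest",
    "score_cohort",
    "embed_sessions",
    "analyze_cohort",
    "run_pipeline",
    "make_report",
    "load_config",
]

logger = logging.getLogger(__name__)

DEFAULTS = {
    "n_resample": 200,
    "bin_size": 10,
    "derivative_weight": 1.0,
    "p_norm": 2,
    "smooth": False,
    "smooth_window_s": 0.25,
    "mds_restarts": 4,
    "seed": 0,
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_hashes: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ------------------------------------------------------------------ scoring


def score_cohort(
    cohort: Cohort,
    n_resample: int = 200,
    p_norm: float = 2,
    bin_size: int = 10,
    derivative_weight: float = 1.0,
    smooth: bool = False,
    smooth_window_s: float = 0.25,
    extra_pools: tuple[Cohort, ...] = (),
) -> pd.DataFrame:
    """Per-path metrics table for a cohort.

    Validity and duration are computed for every path of every task;
    uniqueness is computed for valid option-generation paths against the
    pooled corpus of all valid option-generation paths in this cohort plus
    any ``extra_pools`` (mimicking a multi-study pool).  Invalid paths are
    retained in the table with their validity flag and NaN uniqueness,
    never silently dropped.
    """
    geom = cohort.geometry
    rows: list[dict] = []
    pooled_features = []
    pool_keys: list[int] = []  # row index into `rows` for each pooled path

    def ingest(c: Cohort, record_rows: bool) -> None:
        for sess in c.sessions:
            for traj in sess.trajectories:
                validity = validate_path(traj, geom)
                if record_rows:
                    rows.append(
                        {
                            "participant_id": sess.participant_id,
                            "session_index": sess.session_index,
                            "condition": sess.condition,
                            "task_kind": sess.task_kind,
                            "path_id": traj.path_id,
                            "valid": validity.valid,
                            "invalid_reason": validity.reason,
                            "duration_s": traj.duration,
                            "uniqueness": np.nan,
                            "nearest_neighbour_id": None,
                            "p_norm": p_norm,
                        }
                    )
                if validity.valid and sess.task_kind == "option_generation":
                    source = smooth_trajectory(traj, smooth_window_s) if smooth else traj
                    rp = resample(source, n_resample, participant_id=sess.participant_id)
                    pooled_features.append(
                        build_features(
                            rp, geom, bin_size=bin_size, derivative_weight=derivative_weight
                        )
                    )
                    pool_keys.append(len(rows) - 1 if record_rows else -1)

    ingest(cohort, record_rows=True)
    for extra in extra_pools:
        ingest(extra, record_rows=False)

    if len(pooled_features) >= 2:
        dm = distance_matrix(pooled_features, p_norm=p_norm)
        uniq = uniqueness_from_matrix(dm)
        for k, (row_idx, u, nn) in enumerate(
            zip(pool_keys, uniq["uniqueness"], uniq["nearest_neighbour_id"])
        ):
            if row_idx >= 0:
                rows[row_idx]["uniqueness"] = float(u)
                rows[row_idx]["nearest_neighbour_id"] = nn
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- embedding


def embed_sessions(
    cohort: Cohort,
    n_resample: int = 200,
    p_norm: float = 2,
    bin_size: int = 10,
    derivative_weight: float = 1.0,
    smooth: bool = False,
    smooth_window_s: float = 0.25,
    seed: int = 0,
    n_restarts: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Per-session 2-D MDS embedding and convex-hull exploration area.

    MDS runs on each session's own valid option-generation paths.
    Sessions with fewer than 3 valid paths get hull area 0 with a logged
    warning.  Returns (diversity table, {session key: Embedding2D}).
    """
    geom = cohort.geometry
    ss = np.random.SeedSequence(seed)
    rows = []
    embeddings: dict[tuple[str, int], object] = {}
    sessions = sorted(cohort.iter_sessions("option_generation"), key=lambda s: s.key)
    child_seeds = ss.spawn(len(sessions)) if sessions else []
    for sess, child in zip(sessions, child_seeds):
        feats = []
        for traj in sess.trajectories:
            if not validate_path(traj, geom).valid:
                continue
            source = smooth_trajectory(traj, smooth_window_s) if smooth else traj
            rp = resample(source, n_resample, participant_id=sess.participant_id)
            feats.append(
                build_features(rp, geom, bin_size=bin_size, derivative_weight=derivative_weight)
            )
        sess_seed = int(child.generate_state(1)[0] % (2**31))
        if len(feats) < 3:
            logger.warning(
                "session %s has %d valid paths; hull area set to 0",
                (sess.participant_id, sess.session_index),
                len(feats),
            )
            rows.append(
                {
                    "participant_id": sess.participant_id,
                    "session_index": sess.session_index,
                    "condition": sess.condition,
                    "n_paths": len(feats),
                    "stress": np.nan,
                    "hull_area": 0.0,
                    "seed": sess_seed,
                }
            )
            continue
        dm = distance_matrix(feats, p_norm=p_norm)
        emb = mds_embed(dm, n_dims=2, seed=sess_seed, n_restarts=n_restarts)
        area = convex_hull_area(emb)
        embeddings[(sess.participant_id, sess.session_index)] = emb
        rows.append(
            {
                "participant_id": sess.participant_id,
                "session_index": sess.session_index,
                "condition": sess.condition,
                "n_paths": len(feats),
                "stress": emb.stress,
                "hull_area": area.area,
                "seed": sess_seed,
            }
        )
    return pd.DataFrame(rows), embeddings


# ----------------------------------------------------------------- analysis


def path_level_table(cohort: Cohort, path_metrics: pd.DataFrame) -> pd.DataFrame:
    """Valid option-generation paths with condition and apathy covariates,
    one row per path, for the mixed model."""
    apathy = {
        (s.participant_id, s.session_index): s.covariates.get("apathy", np.nan)
        for s in cohort.iter_sessions("option_generation")
    }
    mask = (path_metrics["task_kind"] == "option_generation") & path_metrics["valid"]
    table = path_metrics.loc[mask].copy()
    table["apathy"] = [
        apathy.get((p, s), np.nan)
        for p, s in zip(table["participant_id"], table["session_index"])
    ]
    return table


def analyze_cohort(
    cohort: Cohort,
    summaries: pd.DataFrame,
    path_metrics: pd.DataFrame,
) -> pd.DataFrame:
    """Run the study's statistical battery appropriate to the design.

    Always: cross-participant fluency vs mean-uniqueness correlation (the
    trade-off).  When motivation covariates exist: motivation correlations
    with fluency/uniqueness/area, dependent-correlation z tests and the
    motivation OLS.  When exactly two conditions exist: paired t tests per
    measure and the duration->uniqueness mixed model.
    """
    results = []

    def push(label: str, res) -> None:
        results.append(
            {
                "analysis": label,
                "method": res.method,
                "estimate": res.estimate,
                "statistic": res.statistic,
                "df": res.df,
                "pvalue": res.pvalue,
                "n": res.extra.get("n", res.extra.get("n_pairs", res.extra.get("n_obs"))),
            }
        )

    first = summaries.sort_values("session_index").groupby("participant_id").head(1)
    ok = first.dropna(subset=["fluency", "mean_uniqueness"])
    if len(ok) >= 3 and ok["fluency"].std() > 0 and ok["mean_uniqueness"].std() > 0:
        push("tradeoff_fluency_uniqueness", correlate(ok["fluency"], ok["mean_uniqueness"]))

    if (
        "motivation" in first.columns
        and first["motivation"].notna().all()
        and len(ok) >= 5  # correlation-difference z needs n > 3 with margin
    ):
        r_fm = correlate(ok["fluency"], ok["motivation"])
        r_um = correlate(ok["mean_uniqueness"], ok["motivation"])
        push("motivation_vs_fluency", r_fm)
        push("motivation_vs_uniqueness", r_um)
        r_fu = correlate(ok["fluency"], ok["mean_uniqueness"])
        push(
            "fisher_z_fluency_vs_uniqueness",
            compare_correlations(
                r_fm.estimate, r_um.estimate, r_fu.estimate, n=len(ok)
            ),
        )
        if "hull_area" in ok.columns and ok["hull_area"].std() > 0:
            r_am = correlate(ok["hull_area"], ok["motivation"])
            push("motivation_vs_hull_area", r_am)
            r_fa = correlate(ok["fluency"], ok["hull_area"])
            push(
                "fisher_z_fluency_vs_area",
                compare_correlations(
                    r_fm.estimate, r_am.estimate, r_fa.estimate, n=len(ok)
                ),
            )
        push("motivation_glm", motivation_glm(ok))

    conditions = sorted(summaries["condition"].unique())
    if len(conditions) == 2:
        base, treat = conditions
        # treated label second for ON/OFF and drug/placebo naming
        if treat in ("OFF", "placebo"):
            base, treat = treat, base
        for measure in ("fluency", "mean_uniqueness", "hull_area"):
            if measure not in summaries.columns:
                continue
            push(
                f"paired_{measure}_{treat}_vs_{base}",
                paired_compare(summaries, measure, treat, base),
            )
        table = path_level_table(cohort, path_metrics)
        if table["participant_id"].nunique() >= 10:
            push(
                "mixed_model_condition_at_fixed_duration",
                tradeoff_mixed_model(table, condition_ref=base),
            )
    return pd.DataFrame(results)


# -------------------------------------------------------------------- runs


def load_config(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute all stages on a configured cohort and write every artifact.

    Config keys: ``seed``; either ``simulate`` (design, n_agents, generator
    overrides) or ``input`` (trajectories/covariates/geometry paths); plus
    any of the scoring defaults (n_resample, p_norm, bin_size, smooth,
    smooth_window_s, mds_restarts); ``pool`` may list extra trajectory CSVs
    whose valid paths join the uniqueness corpus.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULTS, **config}
    seed = int(cfg["seed"])
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "optiongen_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)

    if "input" in cfg:
        spec = cfg["input"]
        traj_path = Path(spec["trajectories"])
        cohort = read_cohort(
            traj_path,
            geometry=spec.get("geometry"),
            covariates_path=spec.get("covariates"),
        )
        manifest.input_hashes[str(traj_path)] = _sha256(traj_path)
    else:
        sim = dict(cfg.get("simulate", {}))
        design = sim.pop("design", "single_session")
        gen = GeneratorConfig(master_seed=seed, **sim)
        cohort = simulate_cohort(gen, design=design)
        traj_path = out / "trajectories.csv"
        write_cohort(cohort, traj_path, covariates_path=out / "covariates.csv")
        manifest.outputs += [str(traj_path), str(out / "covariates.csv")]

    extra_pools = tuple(
        read_cohort(p, geometry=cohort.geometry) for p in cfg.get("pool", [])
    )
    for p in cfg.get("pool", []):
        manifest.input_hashes[str(p)] = _sha256(Path(p))

    score_kwargs = dict(
        n_resample=cfg["n_resample"],
        p_norm=cfg["p_norm"],
        bin_size=cfg["bin_size"],
        derivative_weight=cfg["derivative_weight"],
        smooth=cfg["smooth"],
        smooth_window_s=cfg["smooth_window_s"],
    )
    logger.info("scoring with %s", score_kwargs)
    metrics = score_cohort(cohort, extra_pools=extra_pools, **score_kwargs)
    metrics_path = out / "path_metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.10g", lineterminator="\n")
    manifest.outputs.append(str(metrics_path))

    diversity, embeddings = embed_sessions(
        cohort, seed=seed, n_restarts=cfg["mds_restarts"], **score_kwargs
    )
    div_path = out / "diversity.csv"
    diversity.to_csv(div_path, index=False, float_format="%.10g", lineterminator="\n")
    manifest.outputs.append(str(div_path))

    summaries = summarize(cohort, metrics, diversity)
    summ_path = out / "summaries.csv"
    summaries.to_csv(summ_path, index=False, float_format="%.10g", lineterminator="\n")
    manifest.outputs.append(str(summ_path))

    analyses = analyze_cohort(cohort, summaries, metrics)
    ana_path = out / "analysis.csv"
    analyses.to_csv(ana_path, index=False, float_format="%.10g", lineterminator="\n")
    manifest.outputs.append(str(ana_path))

    report_paths = make_report(out, summaries, analyses, embeddings)
    manifest.outputs += [str(p) for p in report_paths]

    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    return manifest


def make_report(
    out_dir: str | Path,
    summaries: pd.DataFrame,
    analyses: pd.DataFrame,
    embeddings: dict | None = None,
) -> list[Path]:
    """Human-readable text summary plus the standard figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    lines = ["option-generation analysis report", "=" * 34, ""]
    for row in analyses.itertuples(index=False):
        lines.append(
            f"{row.analysis}: {row.method} estimate={row.estimate:.4g} "
            f"stat={row.statistic:.4g} df={row.df:.4g} p={row.pvalue:.4g}"
        )
    txt = out / "report.txt"
    txt.write_text("\n".join(lines) + "\n")
    paths.append(txt)

    if len(summaries):
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(summaries["fluency"], summaries["mean_uniqueness"], s=18)
        ax.set_xlabel("fluency (paths per session)")
        ax.set_ylabel("mean uniqueness (mm feature units)")
        ax.set_title("uniqueness-fluency trade-off")
        fig.tight_layout()
        p = out / "tradeoff_scatter.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    if embeddings:
        keys = sorted(embeddings)[:4]
        fig, axes = plt.subplots(1, len(keys), figsize=(3.2 * len(keys), 3.2))
        axes = np.atleast_1d(axes)
        for ax, key in zip(axes, keys):
            emb = embeddings[key]
            pts = emb.points
            ax.scatter(pts[:, 0], pts[:, 1], s=10)
            hull = convex_hull_area(emb)
            if hull.hull_vertices:
                vv = list(hull.hull_vertices) + [hull.hull_vertices[0]]
                ax.plot(pts[vv, 0], pts[vv, 1], lw=1, color="tab:red")
            ax.set_title(f"{key[0]} s{key[1]}", fontsize=8)
            ax.set_xticks([])
            ax.set_yticks([])
        fig.tight_layout()
        p = out / "embeddings.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
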