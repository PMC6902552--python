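"""End-to-end study orchestration: load → normalize → QC-exclude →
activity summaries → 24 h prediction → window scan → metabolite screen →
gene scan, with an auditable manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._io import config_hash, write_table
from .activity import la24h_targets, read_traces, summaries_to_frame, summarize_traces
from .exceptions import ConfigError
from .metabolome import (
    INTERNAL_STANDARD,
    exclude_incomplete_mice,
    load_metabolome,
    log2_transform,
    normalize_to_internal_standard,
)
from .predictor import PredictorConfig
from .scan import gene_scan, metabolite_screen, predict_la24h, window_scan
from .simulate import SimConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One config governs a run; CLI flags override these fields."""

    traces: str | None = None
    samples: str | None = None
    metabolome: str | None = None
    expression: str | None = None
    outdir: str = "infradian_run"
    internal_standard_name: str = INTERNAL_STANDARD
    metabolome_prenormalized: bool = False
    log2_metabolome: bool = False
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    nominal_p: float = 0.05
    fdr_q: float = 0.1
    bonferroni_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("nominal_p", "fdr_q", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name}={v} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pred_raw = raw.pop("predictor", {}) or {}
        if pred_raw.get("k_grid") is not None:
            pred_raw["k_grid"] = tuple(pred_raw["k_grid"])
        sim_raw = raw.pop("sim", {}) or {}
        for key in ("coupling_lag_window", "infradian_period_days"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        return cls(predictor=PredictorConfig(**pred_raw), sim=SimConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def analysis_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded, so
        identical analyses land identical table headers wherever they run)."""
        d = self.to_dict()
        for key in ("traces", "samples", "metabolome", "expression", "outdir", "log_level"):
            d.pop(key, None)
        return config_hash(d)

    def require_paths(self) -> None:
        for name in ("traces", "samples", "metabolome"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise ConfigError(f"input path '{name}' is missing or does not exist: {p}")


def run_full_study(config: RunConfig) -> Path:
    """Execute the whole analysis and write tables, figures-ready scan
    results, a JSON manifest and a log into ``config.outdir``.

    Returns the run directory.  Any stage failure raises with a
    stage-named message before partial result tables are interpreted.
    """
    config.require_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.analysis_hash()
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("infradian")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        return _run(config, outdir, h)
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(name):
    logger.info("stage: %s", name)


def _run(config: RunConfig, outdir: Path, h: str) -> Path:
    _stage("load")
    traces = read_traces(config.traces, config.samples)
    matrix = load_metabolome(
        config.metabolome,
        internal_standard=config.internal_standard_name,
        normalized=config.metabolome_prenormalized,
    )

    _stage("normalize")
    matrix = normalize_to_internal_standard(matrix)
    if config.log2_metabolome:
        matrix = log2_transform(matrix)

    _stage("exclude")
    matrix, excluded = exclude_incomplete_mice(matrix)
    traces = [t for t in traces if t.mouse_id in set(matrix.mouse_ids)]

    _stage("activity")
    summaries = summarize_traces(traces)
    summary_frame = summaries_to_frame(summaries)
    # align matrix rows to available summaries, by id (never by position)
    common = [m for m in matrix.mouse_ids if m in summary_frame.index]
    matrix.data = matrix.data.loc[common]
    summaries = [s for s in summaries if s.mouse_id in set(common)]
    write_table(summary_frame.loc[common], outdir / "activity_summary.csv", "activity", h)

    _stage("predict-la24h")
    pred = predict_la24h(matrix, summaries, config=config.predictor)
    write_table(pred.to_frame(), outdir / "la24h_prediction.csv", "predict", h)
    write_table(pred.feature_preference.to_frame("preference"), outdir / "la24h_feature_preference.csv", "predict", h)
    (outdir / "la24h_selected_metabolites.txt").write_text(
        "\n".join(pred.selected_features().index) + "\n"
    )

    _stage("screen-metabolites")
    screen = metabolite_screen(matrix, la24h_targets(summaries), config.nominal_p, config.fdr_q)
    write_table(screen.table, outdir / "metabolite_screen.csv", "screen", h)

    _stage("scan-windows")
    wscan = window_scan(matrix, summaries, config=config.predictor, q_threshold=config.fdr_q)
    write_table(wscan.table, outdir / "window_scan.csv", "scan-windows", h)

    _stage("scan-genes")
    gscan = None
    if config.expression and Path(config.expression).exists():
        expression = pd.read_csv(config.expression, comment="#", index_col=0)
        expression = expression.loc[[m for m in matrix.mouse_ids if m in expression.index]]
        gscan = gene_scan(matrix, expression, config=config.predictor, alpha=config.bonferroni_alpha)
        write_table(gscan.table, outdir / "gene_scan.csv", "scan-genes", h)

    _stage("manifest")
    manifest = {
        "package_version": __version__,
        "config_hash": h,
        "seed": config.seed,
        "n_mice": len(matrix.mouse_ids),
        "n_metabolites": len(matrix.features().columns),
        "excluded_mice": excluded,
        "n_windows_scanned": int(len(wscan.table)),
        "n_genes_scanned": int(len(gscan.table)) if gscan is not None else 0,
        "la24h_prediction": {"r": pred.pearson_r, "p": pred.p_value},
        "significant_windows_q": wscan.significant_windows(),
        "metabolite_screen": {"n_nominal": screen.n_nominal, "n_fdr": screen.n_fdr},
        "thresholds": {
            "nominal_p": config.nominal_p,
            "fdr_q": config.fdr_q,
            "bonferroni_alpha": config.bonferroni_alpha,
        },
        "design": {
            "fdr_procedure": "benjamini-hochberg",
            "ranking_statistic": "abs pearson r (training folds only)",
            "inner_criterion": "LOO mean squared error, ties to smallest k",
            "k_grid": list(config.predictor.k_grid) if config.predictor.k_grid else f"1..min({config.predictor.max_k}, n_train-2)",
            "test_sidedness": "two-sided",
            "standardize": config.predictor.standardize,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("run complete: %s", outdir)
    return outdir
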