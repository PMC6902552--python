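"""Synthetic cohorts with known metabolome–activity coupling.

The generator emulates the study design this pipeline analyzes: singly
housed mice under a 12:12 light/dark cycle whose home-cage locomotor
activity (LA) oscillates on an infradian time scale — each mouse's daily
activity waxes and wanes with a period of roughly 10–20 days — on top of
the usual nocturnal (dark-phase) elevation.  Blood is sampled at ZT6 on the
final monitored day; a chosen subset of blood metabolites is linearly
coupled to the distance traveled in a configurable lag window before
sampling, and a subset of hippocampal transcripts is linearly coupled to
the latent infradian state at sampling.  Everything else is noise.

Each mouse's trace is

    distance(bin) = baseline * (1 + A sin(2*pi*t/T_i + phi_i)) * circ(ZT) * noise

with ``T_i`` uniform on the configured period band, ``phi_i`` uniform
phase, ``circ`` scaling dark bins by the dark/light ratio, and
multiplicative lognormal (or additive Gaussian) bin noise, truncated at
zero.  A coupled metabolite ``j`` with lag window ``[a, b)`` hours before
sampling is

    x_ij = baseline_j + beta_j * (W_i - mean(W)) + eps_ij,
    W_i  = distance traveled by mouse i in [sampling - b, sampling - a)

with ``beta_j`` of random sign and the noise variance set so the population
R^2 between ``x_j`` and ``W`` equals ``coupling_strength`` exactly.  The
raw table is then multiplied per mouse by a simulated measurement
efficiency that also appears as the internal-standard column, so the
normalization stage has real work to do.

All randomness flows from the single ``seed`` through one
``numpy.random.Generator``; identical configs give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import get_window

from ._io import config_hash, write_table
from .activity import ActivityTrace, write_traces
from .exceptions import ConfigError, InsufficientDataError
from .metabolome import INTERNAL_STANDARD, MetabolomeMatrix

#: hippocampal circadian-related genes scanned by default
DEFAULT_GENES = ("Lonrf1", "Cys1", "Hist1h1c", "Tef", "Ak4", "Arntl", "Sfpq")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults reproduce the analyzed study scale: 35 mice, 106 metabolites,
    an infradian period band of 10–20 days over 75 monitored days, ZT6
    sampling, and a coupled metabolite set explaining about half the
    variance of the 24 h LA window (the interval 6–30 h before sampling).
    """

    n_mice: int = 35
    n_metabolites: int = 106
    n_coupled: int = 10
    coupling_lag_window: tuple[float, float] = (6.0, 30.0)
    coupling_strength: float = 0.5
    infradian_period_days: tuple[float, float] = (10.0, 20.0)
    infradian_amplitude: float = 0.6
    circadian_darklight_ratio: float = 3.0
    bin_hours: float = 1.0
    trace_days: int = 75
    noise_model: str = "lognormal"
    noise_scale: float = 0.3
    n_genes: int = 7
    n_coupled_genes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coupled > self.n_metabolites:
            raise ConfigError("n_coupled must not exceed n_metabolites")
        if not 0.0 <= self.coupling_strength < 1.0:
            raise ConfigError("coupling_strength must be in [0, 1)")
        lo, hi = self.infradian_period_days
        if not (1.0 <= lo <= hi <= self.trace_days):
            raise ConfigError("infradian_period_days must lie within [1, trace_days]")
        if self.bin_hours <= 0 or abs(24.0 / self.bin_hours - round(24.0 / self.bin_hours)) > 1e-9:
            raise ConfigError("bin_hours must divide 24")
        if not 0.0 <= self.infradian_amplitude < 1.0:
            raise ConfigError("infradian_amplitude must be in [0, 1)")
        if self.circadian_darklight_ratio < 1.0:
            raise ConfigError("circadian_darklight_ratio must be >= 1")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ConfigError("noise_model must be 'gaussian' or 'lognormal'")
        if self.trace_days < 4:
            raise ConfigError("trace_days must be >= 4 to cover the 72 h lookback")
        a, b = self.coupling_lag_window
        if not 0.0 <= a < b:
            raise ConfigError("coupling_lag_window must be an increasing hours-before-sampling interval")
        if self.n_coupled_genes > self.n_genes:
            raise ConfigError("n_coupled_genes must not exceed n_genes")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Bookkeeping of what was planted, for recovery and type-I tests."""

    coupled_metabolite_ids: list[str]
    lag_windows: dict[str, tuple[float, float]]
    coefficients: dict[str, float]
    coupled_gene_ids: list[str]
    latent_phase: dict[str, float]     # infradian phase (rad, mod 2pi) at sampling
    latent_state: dict[str, float]     # sin of that phase
    periods_days: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["lag_windows"] = {k: tuple(v) for k, v in d["lag_windows"].items()}
        return cls(**d)


def _metabolite_names(n: int) -> list[str]:
    return [f"met_{j + 1:03d}" for j in range(n)]


def _gene_names(n: int) -> list[str]:
    if n <= len(DEFAULT_GENES):
        return list(DEFAULT_GENES[:n])
    return list(DEFAULT_GENES) + [f"gene_{j + 1:03d}" for j in range(n - len(DEFAULT_GENES))]


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[ActivityTrace], MetabolomeMatrix, pd.DataFrame, GroundTruth]:
    """Generate traces, a raw metabolome table (with internal-standard
    column), a log2 gene-expression table, and the ground truth.

    Returns
    -------
    traces : list of ActivityTrace
    metabolome : MetabolomeMatrix
        Raw (pre-normalization) values including the internal-standard
        column; run :func:`~infradian.metabolome.normalize_to_internal_standard`
        before analysis.
    expression : DataFrame
        Mice × genes log2 expression values.
    truth : GroundTruth
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mouse_ids = [f"mouse_{i + 1:02d}" for i in range(cfg.n_mice)]

    n_bins = int(round(cfg.trace_days * 24.0 / cfg.bin_hours))
    bin_starts = np.arange(n_bins) * cfg.bin_hours
    sampling_time = 24.0 * (cfg.trace_days - 1) + 6.0
    zt_mid = (bin_starts + cfg.bin_hours / 2.0) % 24.0
    circ = np.where(zt_mid >= 12.0, cfg.circadian_darklight_ratio, 1.0)
    baseline_cm_per_bin = 1500.0 * cfg.bin_hours  # ~36 m/h scale before modulation

    periods = rng.uniform(*cfg.infradian_period_days, size=cfg.n_mice)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_mice)

    traces: list[ActivityTrace] = []
    for i, mid in enumerate(mouse_ids):
        infradian = 1.0 + cfg.infradian_amplitude * np.sin(
            2.0 * np.pi * bin_starts / (24.0 * periods[i]) + phases[i]
        )
        mean = baseline_cm_per_bin * infradian * circ
        if cfg.noise_scale == 0.0:
            dist = mean
        elif cfg.noise_model == "lognormal":
            sigma = cfg.noise_scale
            dist = mean * np.exp(rng.normal(0.0, sigma, size=n_bins) - sigma**2 / 2.0)
        else:
            dist = mean + rng.normal(0.0, cfg.noise_scale, size=n_bins) * mean
        dist = np.maximum(dist, 0.0)
        traces.append(
            ActivityTrace(
                mouse_id=mid,
                bin_starts=bin_starts,
                distances=dist,
                bin_hours=cfg.bin_hours,
                sampling_time=sampling_time,
            )
        )

    # --- metabolome -------------------------------------------------------
    met_names = _metabolite_names(cfg.n_metabolites)
    n_coupled = cfg.n_coupled if cfg.coupling_strength > 0.0 else 0
    coupled_idx = np.sort(rng.choice(cfg.n_metabolites, size=n_coupled, replace=False)) if n_coupled else np.array([], int)
    coupled_names = [met_names[j] for j in coupled_idx]

    a, b = cfg.coupling_lag_window
    W = np.array([t.interval_distance(sampling_time - b, sampling_time - a) for t in traces])
    W_centered = W - W.mean()
    sd_W = W.std()

    X = np.empty((cfg.n_mice, cfg.n_metabolites))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_metabolites)  # drawn for all, used for coupled
    noise = rng.normal(0.0, 1.0, size=(cfg.n_mice, cfg.n_metabolites))
    coefficients: dict[str, float] = {}
    lag_windows: dict[str, tuple[float, float]] = {}
    rho2 = cfg.coupling_strength
    coupled_set = set(coupled_idx.tolist())
    for j in range(cfg.n_metabolites):
        if j in coupled_set and sd_W > 0:
            beta = signs[j] / sd_W  # unit signal SD in metabolite units
            sigma_eps = np.sqrt((1.0 - rho2) / rho2)
            signal = beta * W_centered
            X[:, j] = 8.0 * np.sqrt(1.0 + sigma_eps**2) + signal + sigma_eps * noise[:, j]
            coefficients[met_names[j]] = float(beta)
            lag_windows[met_names[j]] = (a, b)
        else:
            X[:, j] = 8.0 + noise[:, j]
    X = np.maximum(X, 0.0)  # concentrations are nonnegative; offsets make clipping astronomically rare

    efficiency = np.exp(rng.normal(0.0, 0.1, size=cfg.n_mice))
    raw = X * efficiency[:, None]
    table = pd.DataFrame(raw, index=pd.Index(mouse_ids, name="mouse_id"), columns=met_names)
    table[INTERNAL_STANDARD] = efficiency
    metabolome = MetabolomeMatrix(data=table, internal_standard=INTERNAL_STANDARD, normalized=False)

    # --- gene expression --------------------------------------------------
    gene_names = _gene_names(cfg.n_genes)
    n_cgenes = cfg.n_coupled_genes if cfg.coupling_strength > 0.0 else 0
    cgene_idx = np.sort(rng.choice(cfg.n_genes, size=n_cgenes, replace=False)) if n_cgenes else np.array([], int)
    latent_phase = (2.0 * np.pi * sampling_time / (24.0 * periods) + phases) % (2.0 * np.pi)
    latent = np.sin(latent_phase)
    latent_centered = latent - latent.mean()
    sd_latent = latent.std()

    G = np.empty((cfg.n_mice, cfg.n_genes))
    gnoise = rng.normal(0.0, 1.0, size=(cfg.n_mice, cfg.n_genes))
    gsigns = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    cgene_set = set(cgene_idx.tolist())
    for g in range(cfg.n_genes):
        if g in cgene_set and sd_latent > 0:
            gamma = gsigns[g] / sd_latent
            sigma_eps = np.sqrt((1.0 - rho2) / rho2)
            G[:, g] = 8.0 + gamma * latent_centered + sigma_eps * gnoise[:, g]
        else:
            G[:, g] = 8.0 + gnoise[:, g]
    expression = pd.DataFrame(G, index=pd.Index(mouse_ids, name="mouse_id"), columns=gene_names)

    truth = GroundTruth(
        coupled_metabolite_ids=coupled_names,
        lag_windows=lag_windows,
        coefficients=coefficients,
        coupled_gene_ids=[gene_names[g] for g in cgene_idx],
        latent_phase={m: float(p) for m, p in zip(mouse_ids, latent_phase)},
        latent_state={m: float(s) for m, s in zip(mouse_ids, latent)},
        periods_days={m: float(p) for m, p in zip(mouse_ids, periods)},
    )
    return traces, metabolome, expression, truth


def empirical_period(trace: ActivityTrace, nfft: int = 1 << 14) -> float:
    """Dominant infradian period (days) of a trace, from its daily totals.

    Daily totals are Hann-windowed and zero-padded before the periodogram;
    the spectral peak strictly below 1 cycle/day gives the period.  Returns
    ``nan`` when there is no infradian variation to detect (e.g. a constant
    trace).  Reliable only when the trace is at least twice the period.
    """
    n_days = int(trace.duration_days)
    if n_days < 2:
        raise InsufficientDataError(f"{trace.mouse_id}: need >= 2 full days, have {trace.duration_days:.2f}")
    bins_per_day = int(round(24.0 / trace.bin_hours))
    daily = trace.distances[: n_days * bins_per_day].reshape(n_days, bins_per_day).sum(axis=1)
    daily = daily - daily.mean()
    if not np.any(np.abs(daily) > 1e-9 * max(1.0, np.abs(trace.distances).max())):
        return float("nan")
    tapered = daily * get_window("hann", n_days)
    spectrum = np.abs(np.fft.rfft(tapered, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0)  # cycles per day
    valid = (freqs > 1.0 / n_days) & (freqs < 1.0)
    if not valid.any() or spectrum[valid].max() <= 0:
        return float("nan")
    peak = freqs[valid][np.argmax(spectrum[valid])]
    return float(1.0 / peak)


def write_cohort(
    outdir: str | Path,
    traces: Sequence[ActivityTrace],
    metabolome: MetabolomeMatrix,
    expression: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
) -> dict[str, Path]:
    """Write the cohort as plain tabular text plus a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config_hash(config.to_dict())
    paths = {
        "traces": outdir / "traces.csv",
        "samples": outdir / "samples.csv",
        "metabolome": outdir / "metabolome.csv",
        "expression": outdir / "expression.csv",
        "truth": outdir / "truth.json",
    }
    write_traces(traces, paths["traces"], paths["samples"], conf_hash=h)
    write_table(metabolome.data, paths["metabolome"], stage="simulate:metabolome", conf_hash=h)
    write_table(expression, paths["expression"], stage="simulate:expression", conf_hash=h)
    truth.to_json(paths["truth"])
    return paths
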