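"""End-to-end study analysis: preprocessing -> spectral -> metrics ->
forecasting -> regression models, with a reproducible result bundle.

``analyze_study`` turns raw recordings plus behavioral tables into the
group-level windowed FAA and ISC series and whole-video FAA values;
``run_pipeline`` wraps the whole flow (optionally starting from the
synthetic generator), writes CSV/JSON results, and records a provenance
manifest (config hash, seed, package versions).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .forecasting import MomentwiseForecast, MomentwiseForecastResults
from .metrics import POWER_FLOOR, isc, isc_channel_map
from .models import (FundingAmountResults, InterestLMMResults,
                     fit_amount_regression, fit_interest_lmm)
from .montage import FAA_PAIR, ISC_CHANNELS
from .power import PowerSimResult, power_table
from .preprocessing import preprocess_recording
from .recording import EEGRecording
from .spectral import (ENVELOPE_FS, BandPowerSeries, RollingWindowSpec,
                       morlet_alpha_envelope, welch_band_power, window_average)
from .synthetic import SimConfig, generate_study
from .tables import StudyTables


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the neural analysis stages."""

    low: float = 0.3
    high: float = 50.0
    band: tuple[float, float] = (8.0, 13.0)
    window_length: float = 5.0
    window_step: float = 1.0
    t_max: float = 63.0
    n_cycles: float = 7.0
    env_fs: float = ENVELOPE_FS
    isc_channels: tuple[str, ...] = ISC_CHANNELS
    #: None = only the channels the requested metrics need; "all" = every EEG channel
    morlet_channels: tuple[str, ...] | str | None = None
    metrics: tuple[str, ...] = ("faa", "isc")
    #: also compute per-subject whole-video Welch FAA (needed by the models)
    whole_video_faa: bool = True


@dataclass
class StudyAnalysis:
    """Group-level neural series for one study."""

    video_ids: list[str]
    window_spec: RollingWindowSpec
    faa_windows: np.ndarray | None          # (n_windows, n_videos) group FAA
    isc_windows: np.ndarray | None          # (n_windows, n_videos) mean ISC
    faa_whole: pd.DataFrame | None          # subject_id, video_id, faa (Welch)
    envelopes: dict[str, dict[str, BandPowerSeries]] | None = None
    params: AnalysisParams | None = None

    def faa_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.faa_windows, columns=self.video_ids)
        df.insert(0, "window_start", self.window_spec.starts)
        return df

    def isc_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.isc_windows, columns=self.video_ids)
        df.insert(0, "window_start", self.window_spec.starts)
        return df


def group_faa_matrix(envelopes: Mapping[str, Mapping[str, BandPowerSeries]],
                     video_ids: Sequence[str],
                     wspec: RollingWindowSpec) -> np.ndarray:
    """Across-subject mean windowed FAA, shape (n_windows, n_videos)."""
    out = np.empty((wspec.n_windows, len(video_ids)))
    for j, v in enumerate(video_ids):
        per_subj = []
        for env in envelopes[v].values():
            wp = window_average(env, wspec)
            p3 = wp[env.channels.index("F3")]
            p4 = wp[env.channels.index("F4")]
            per_subj.append(np.log(np.maximum(p4, POWER_FLOOR))
                            - np.log(np.maximum(p3, POWER_FLOOR)))
        out[:, j] = np.mean(per_subj, axis=0)
    return out


def group_isc_matrix(envelopes: Mapping[str, Mapping[str, BandPowerSeries]],
                     video_ids: Sequence[str], wspec: RollingWindowSpec,
                     channels: Sequence[str] = ISC_CHANNELS) -> np.ndarray:
    """Mean pairwise ISC per window per video, shape (n_windows, n_videos)."""
    out = np.empty((wspec.n_windows, len(video_ids)))
    for j, v in enumerate(video_ids):
        for w, win in enumerate(wspec.windows):
            out[w, j] = isc(envelopes[v], win, channels=channels).mean_isc
    return out


def _needed_channels(params: AnalysisParams, all_eeg: Sequence[str]) -> tuple[str, ...]:
    if params.morlet_channels == "all":
        return tuple(all_eeg)
    if params.morlet_channels is not None:
        return tuple(params.morlet_channels)
    need: list[str] = []
    if "faa" in params.metrics:
        need += list(FAA_PAIR)
    if "isc" in params.metrics:
        need += [c for c in params.isc_channels if c not in need]
    return tuple(need)


def analyze_study(recordings: Sequence[EEGRecording], tables: StudyTables,
                  params: AnalysisParams | None = None,
                  keep_envelopes: bool = False) -> StudyAnalysis:
    """Run preprocessing, spectral estimation, and the FAA/ISC metrics.

    Returns group-level windowed series aligned on a common rolling-window
    grid (truncated at the shortest video, at most ``t_max``) plus
    per-subject whole-video FAA from Welch PSDs.
    """
    params = params or AnalysisParams()
    if tables.videos is None:
        raise ValueError("tables must include per-video durations (videos table)")
    durations = dict(zip(tables.videos["video_id"], tables.videos["duration_s"]))
    video_ids = sorted(durations)
    t_max = min(params.t_max, min(durations.values()))
    wspec = RollingWindowSpec(params.window_length, params.window_step, t_max)

    envelopes: dict[str, dict[str, BandPowerSeries]] = {v: {} for v in video_ids}
    faa_whole_rows = []
    want_faa = "faa" in params.metrics
    want_isc = "isc" in params.metrics
    morlet_chs = _needed_channels(params, recordings[0].eeg_channels)

    for rec in recordings:
        epochs, _ = preprocess_recording(rec, durations,
                                         low=params.low, high=params.high)
        for ep in epochs:
            env = morlet_alpha_envelope(ep, band=params.band,
                                        n_cycles=params.n_cycles,
                                        channels=morlet_chs)
            envelopes[ep.video_id][ep.subject_id] = env.resample(params.env_fs)
            if want_faa and params.whole_video_faa:
                pw = welch_band_power(ep, band=params.band, channels=FAA_PAIR)
                faa_whole_rows.append({
                    "subject_id": ep.subject_id, "video_id": ep.video_id,
                    "faa": float(np.log(max(pw["F4"], POWER_FLOOR))
                                 - np.log(max(pw["F3"], POWER_FLOOR))),
                })

    faa_windows = isc_windows = None
    if want_faa:
        faa_windows = group_faa_matrix(envelopes, video_ids, wspec)
    if want_isc:
        isc_windows = group_isc_matrix(envelopes, video_ids, wspec,
                                       params.isc_channels)

    return StudyAnalysis(
        video_ids=video_ids, window_spec=wspec,
        faa_windows=faa_windows, isc_windows=isc_windows,
        faa_whole=pd.DataFrame(faa_whole_rows) if faa_whole_rows else None,
        envelopes=envelopes if keep_envelopes else None,
        params=params,
    )


# ---------------------------------------------------------------------------
# forecasting / modelling conveniences on top of an analysis
# ---------------------------------------------------------------------------

def forecast_population_interest(analysis: StudyAnalysis, tables: StudyTables,
                                 method: str = "pearson", n_boot: int = 0,
                                 seed: int | None = None) -> MomentwiseForecastResults:
    """Window-wise correlation of group FAA with population interest."""
    pop = tables.population.set_index("video_id").loc[analysis.video_ids, "pop_interest"]
    model = MomentwiseForecast(analysis.faa_windows, pop.to_numpy(),
                               windows=analysis.window_spec.windows,
                               metric_name="FAA", outcome_name="population interest",
                               video_ids=analysis.video_ids)
    return model.fit(method=method, n_boot=n_boot, seed=seed)


def forecast_deal_outcomes(analysis: StudyAnalysis, tables: StudyTables,
                           method: str = "pearson", n_boot: int = 0,
                           seed: int | None = None) -> MomentwiseForecastResults:
    """Window-wise point-biserial correlation of mean ISC with deal outcome."""
    deal = tables.outcomes.set_index("video_id").loc[analysis.video_ids, "deal"]
    model = MomentwiseForecast(analysis.isc_windows, deal.to_numpy(dtype=float),
                               windows=analysis.window_spec.windows,
                               metric_name="ISC", outcome_name="deal",
                               video_ids=analysis.video_ids)
    return model.fit(method=method, n_boot=n_boot, seed=seed)


def interest_lmm_table(analysis: StudyAnalysis, tables: StudyTables) -> pd.DataFrame:
    """Long-format table joining interest composites with FAA, DC, sentiment."""
    df = tables.interest_composite()
    df = df.merge(analysis.faa_whole, on=["subject_id", "video_id"])
    df = df.merge(tables.dc_composite(), on="subject_id")
    if tables.sentiment is not None:
        df = df.merge(tables.sentiment[["video_id", "joy"]], on="video_id")
    return df


def amount_video_table(analysis: StudyAnalysis, tables: StudyTables) -> pd.DataFrame:
    """Per-video table: amount, group-mean FAA, stated prediction, sentiment."""
    df = tables.video_table()
    faa_mean = (analysis.faa_whole.groupby("video_id")["faa"].mean()
                .rename("faa").reset_index())
    pred = (tables.ratings.groupby("video_id")["deal_prediction"].mean()
            .rename("stated_prediction").reset_index())
    return df.merge(faa_mean, on="video_id").merge(pred, on="video_id")


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One reproducible pipeline run.

    When ``simulate`` is true the study comes from the synthetic generator
    (``sim``); otherwise recordings and tables are loaded from
    ``input_dir`` (internal containers plus CSV tables).
    """

    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None
    output_dir: str = "results"
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    n_boot: int = 5000
    rank_order: bool = False
    run_models: bool = True
    run_power: bool = False
    run_channel_map: bool = False
    power_rhos: tuple[float, ...] = (0.10, 0.30, 0.50)
    power_iters: int = 5000
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str, sort_keys=True, indent=1)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Everything one pipeline run produced."""

    config: RunConfig
    tables: StudyTables
    analysis: StudyAnalysis
    faa_forecast: MomentwiseForecastResults | None = None
    isc_forecast: MomentwiseForecastResults | None = None
    lmm: InterestLMMResults | None = None
    lmm_baseline: InterestLMMResults | None = None
    amount: FundingAmountResults | None = None
    channel_map: pd.DataFrame | None = None
    power: list[PowerSimResult] | None = None


def _versions() -> dict[str, str]:
    import mne
    import scipy
    import statsmodels

    from . import __version__
    return {"neuroforecast": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__, "mne": mne.__version__}


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the configured stages and write the result bundle.

    Any stage failure aborts with the stage name prefixed to the error.
    """
    stage = "inputs"
    try:
        if config.simulate:
            recordings, tables, _truth = generate_study(config.sim, seed=config.seed)
        else:
            from .io import read_eeg, read_tables
            in_dir = Path(config.input_dir)
            tables = read_tables(in_dir)
            recordings = [read_eeg(p) for p in sorted(in_dir.glob("*.json"))
                          if p.stem != "manifest"]
            if not recordings:
                raise FileNotFoundError(f"no recordings found in {in_dir}")

        stage = "analysis"
        analysis = analyze_study(recordings, tables, config.analysis,
                                 keep_envelopes=config.run_channel_map)
        bundle = ResultBundle(config=config, tables=tables, analysis=analysis)
        method = "rank" if config.rank_order else "pearson"

        stage = "forecasting"
        if analysis.faa_windows is not None:
            bundle.faa_forecast = forecast_population_interest(
                analysis, tables, method=method, n_boot=config.n_boot,
                seed=config.seed)
        if analysis.isc_windows is not None:
            bundle.isc_forecast = forecast_deal_outcomes(
                analysis, tables, method=method, n_boot=config.n_boot,
                seed=config.seed + 1)

        if config.run_models and analysis.faa_whole is not None:
            stage = "models"
            lmm_df = interest_lmm_table(analysis, tables)
            fixed = ["faa", "dc"] + (["joy"] if "joy" in lmm_df.columns else [])
            bundle.lmm = fit_interest_lmm(lmm_df, fixed)
            bundle.lmm_baseline = fit_interest_lmm(lmm_df, ["dc"])
            amt = amount_video_table(analysis, tables)
            preds = ["faa", "stated_prediction"] + (
                ["joy"] if "joy" in amt.columns else [])
            bundle.amount = fit_amount_regression(amt, preds)

        if config.run_channel_map and analysis.envelopes is not None:
            stage = "channel_map"
            bundle.channel_map = isc_channel_map(analysis.envelopes, tables.outcomes)

        if config.run_power:
            stage = "power"
            bundle.power = power_table(list(config.power_rhos),
                                       iters=config.power_iters,
                                       seed=config.seed)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    _write_bundle(bundle)
    return bundle


def _write_bundle(bundle: ResultBundle) -> None:
    out = Path(bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis = bundle.analysis
    if analysis.faa_windows is not None:
        analysis.faa_frame().to_csv(out / "faa_windows.csv", index=False)
    if analysis.isc_windows is not None:
        analysis.isc_frame().to_csv(out / "isc_windows.csv", index=False)
        deal = bundle.tables.outcomes.set_index("video_id").loc[
            analysis.video_ids, "deal"].to_numpy()
        traj = pd.DataFrame({
            "window_start": analysis.window_spec.starts,
            "isc_funded": analysis.isc_windows[:, deal == 1].mean(axis=1),
            "isc_unfunded": analysis.isc_windows[:, deal == 0].mean(axis=1)
            if (deal == 0).any() else np.nan,
        })
        traj.to_csv(out / "isc_trajectories.csv", index=False)
    for name, fc in [("faa_forecast", bundle.faa_forecast),
                     ("isc_forecast", bundle.isc_forecast)]:
        if fc is not None:
            fc.frame.to_csv(out / f"{name}.csv", index=False)
    if bundle.lmm is not None:
        (out / "lmm_summary.txt").write_text(
            bundle.lmm.summary() + "\n\nbaseline (DC only):\n"
            + bundle.lmm_baseline.summary() + "\n")
    if bundle.amount is not None:
        bundle.amount.table.to_csv(out / "amount_regression.csv")
        (out / "amount_summary.txt").write_text(bundle.amount.summary() + "\n")
    if bundle.channel_map is not None:
        bundle.channel_map.to_csv(out / "isc_channel_map.csv", index=False)
    if bundle.power is not None:
        pd.DataFrame([{"rho": p.rho, "power": p.power,
                       "ci_lo": p.ci[0], "ci_hi": p.ci[1],
                       "n_videos": p.n_videos, "iterations": p.iterations}
                      for p in bundle.power]).to_csv(out / "power.csv", index=False)
    manifest = {
        "config_hash": bundle.config.config_hash,
        "seed": bundle.config.seed,
        "config": json.loads(bundle.config.to_json()),
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
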