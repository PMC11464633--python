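"""End-to-end orchestration: simulate -> analyze -> report.

``run_pipeline`` loads every discoverable session, runs the applicable
modality analyses (skipping modalities that are absent or ineligible,
with the reason logged per session), computes group-level permutation
statistics, and writes tidy result tables plus a JSON run summary with
the effective configuration, its hash, and per-session QC counts.
Every constant of the analysis (band edges, window lengths, epoch
specs, R-R bounds, permutation count, alpha, MCID thresholds) lives in
:class:`RunConfig` as an overridable default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Modality
from . import clinical as clinical_mod
from .eeg import compute_band_power, period_summary, topographic_contrast
from .emg import SamplingGateError, emg_session_summary
from .hrv import HRV_FEATURES, NoPeaksError, RRQualityError, hrv_session_summary
from .io_bids import discover_sessions, load_session, write_results, write_synthetic_dataset
from .preprocess import auto_artifact_mask, bandpass, notch_comb, remove_ocular_component
from .stats import compare_periods

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "cli"]


@dataclass
class RunConfig:
    """Every tunable constant of the analysis, with study defaults."""

    seed: int = 0
    window_minutes: dict = field(default_factory=lambda: {"PRE": 5.0, "MTI": 15.0, "POST": 5.0})
    eeg_band_edges: tuple = ((1.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 18.0), (18.0, 30.0))
    eeg_filter: tuple = (1.0, 30.0)
    ecg_filter: tuple = (1.0, 40.0)
    emg_filter: tuple = (20.0, 200.0)
    notch_base: float = 60.0
    eeg_epoch: tuple = (3.0, 1.5)     # length, overlap (s)
    emg_epoch: tuple = (2.0, 1.0)
    rr_bounds_ms: tuple = (300.0, 1500.0)
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.4)
    n_permutations: int = 1600
    alpha: float = 0.05
    mcid: dict = field(default_factory=lambda: dict(clinical_mod.MCID))
    label_map: dict = field(default_factory=lambda: {"PRE": "PRE", "MTI": "MTI", "POST": "POST"})
    artifact_z_threshold: float = 5.0
    ica_blink_threshold: float = 0.5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not 0 < cfg.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if cfg.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        return cfg


def _analyze_eeg(rec, seg, cfg: RunConfig, session_id: str, qc: dict):
    filtered = bandpass(rec, *cfg.eeg_filter)
    mask = auto_artifact_mask(filtered, cfg.artifact_z_threshold)
    qc["eeg_artifact_spans"] = len(mask)
    cleaned, info = remove_ocular_component(
        filtered, threshold=cfg.ica_blink_threshold, seed=cfg.seed)
    qc["eeg_ica_removed"] = info["removed"]
    series = compute_band_power(
        cleaned, seg, window_minutes=cfg.window_minutes,
        epoch_length=cfg.eeg_epoch[0], overlap=cfg.eeg_epoch[1], mask=mask)
    summary = period_summary(series)
    summary.insert(0, "recording", session_id)
    qc["eeg_epochs"] = len(series.periods)
    return summary


def _analyze_ecg(rec, seg, cfg: RunConfig, session_id: str, qc: dict):
    filtered = bandpass(rec, *cfg.ecg_filter)
    result = hrv_session_summary(filtered, seg, window_minutes=cfg.window_minutes)
    qc["rr_interpolated"] = result["n_interpolated"]
    rows = []
    for period, feats in result["per_period"].items():
        for feat in HRV_FEATURES:
            rows.append({"recording": session_id, "period": period,
                         "feature": feat, "value": feats[feat]})
    return pd.DataFrame(rows)


def _analyze_emg(rec, seg, cfg: RunConfig, session_id: str, qc: dict):
    filtered = bandpass(rec, *cfg.emg_filter)
    filtered = notch_comb(filtered, base=cfg.notch_base, up_to=cfg.emg_filter[1])
    result = emg_session_summary(
        filtered, seg, window_minutes=cfg.window_minutes,
        epoch_length=cfg.emg_epoch[0], overlap=cfg.emg_epoch[1])
    qc["emg_epochs"] = len(result["epoch_rms"])
    rows = []
    for period, feats in result["per_period"].items():
        for feat in ("rms_z", "mnf"):
            rows.append({"recording": session_id, "period": period,
                         "feature": feat, "value": feats[feat]})
    return pd.DataFrame(rows)


def run_pipeline(
    data_root,
    out_dir,
    config: RunConfig | None = None,
    clinical_path=None,
    overwrite: bool = False,
) -> dict:
    """Analyze every session under ``data_root`` and write tidy tables.

    Per-modality failures (absent channel, sampling gate, lead
    disconnection) are logged per session and the run continues; it
    fails only if zero sessions complete.
    """
    cfg = config or RunConfig()
    manifests = discover_sessions(data_root)
    eeg_rows, hrv_rows, emg_rows = [], [], []
    qc_all, errors = {}, {}
    for man in manifests:
        session_id = f"{man.subject}_{man.session}"
        qc: dict = {}
        try:
            session = load_session(man, label_map=cfg.label_map)
        except Exception as exc:  # unreadable session: record and move on
            errors[session_id] = f"load: {exc}"
            continue
        seg = session.segmentation
        eeg = session.get(Modality.EEG)
        if eeg is not None:
            try:
                eeg_rows.append(_analyze_eeg(eeg, seg, cfg, session_id, qc))
            except Exception as exc:
                errors[session_id] = f"eeg: {exc}"
        ecg = session.get(Modality.ECG)
        if ecg is None:
            qc["ecg_skip"] = "no ECG channel (lead disconnection or not recorded)"
        else:
            try:
                hrv_rows.append(_analyze_ecg(ecg, seg, cfg, session_id, qc))
            except (NoPeaksError, RRQualityError, ValueError) as exc:
                qc["ecg_skip"] = str(exc)
        emg = session.get(Modality.EMG)
        if emg is None:
            qc["emg_skip"] = "no EMG channel"
        elif not emg.emg_analysis_eligible:
            qc["emg_skip"] = (f"sampling rate {emg.sampling_rate:g} Hz below the "
                              "512 Hz analysis gate")
        else:
            try:
                emg_rows.append(_analyze_emg(emg, seg, cfg, session_id, qc))
            except (SamplingGateError, ValueError) as exc:
                qc["emg_skip"] = str(exc)
        for key, reason in qc.items():
            if key.endswith("_skip"):
                logger.info("%s: skipping %s: %s", session_id, key[:-5], reason)
        qc_all[session_id] = qc
    tables: dict[str, pd.DataFrame] = {}
    stats_frames = []
    if eeg_rows:
        eeg_table = pd.concat(eeg_rows, ignore_index=True)
        tables["eeg_bandpower"] = eeg_table
        contrasts = []
        for pair in (("MTI", "PRE"), ("POST", "PRE")):
            con = topographic_contrast(eeg_table, contrast=pair,
                                       n_perm=cfg.n_permutations, seed=cfg.seed,
                                       alpha=cfg.alpha)
            con.insert(0, "pair", f"{pair[0]}-{pair[1]}")
            contrasts.append(con)
        tables["eeg_contrast"] = pd.concat(contrasts, ignore_index=True)
    for name, rows in (("hrv", hrv_rows), ("emg", emg_rows)):
        if not rows:
            continue
        table = pd.concat(rows, ignore_index=True)
        tables[name] = table
        stats = compare_periods(table, n_perm=cfg.n_permutations,
                                seed=cfg.seed, alpha=cfg.alpha)
        stats.insert(0, "modality", name)
        stats_frames.append(stats)
    if stats_frames:
        tables["stats"] = pd.concat(stats_frames, ignore_index=True)
    if clinical_path is not None:
        ctab = clinical_mod.load_clinical_table(clinical_path)
        tables["clinical"] = clinical_mod.clinical_summary_table(
            ctab, n_perm=cfg.n_permutations, seed=cfg.seed)
    n_complete = len({sid for sid in qc_all} - set(errors))
    if n_complete == 0:
        raise RuntimeError(f"no session completed; errors: {errors}")
    config_dict = cfg.to_dict()
    config_dict["qc"] = qc_all
    config_dict["errors"] = errors
    paths = write_results(tables, out_dir, seed=cfg.seed, config=config_dict,
                          overwrite=overwrite)
    return {
        "tables": tables, "paths": paths, "qc": qc_all, "errors": errors,
        "n_sessions": len(manifests),
        "n_eeg": len(eeg_rows), "n_ecg": len(hrv_rows), "n_emg": len(emg_rows),
    }


# ---------------------------------------------------------------------------
# command-line interface

@click.group()
@click.version_option(__version__)
def cli():
    """Music-therapy session electrophysiology analysis."""


@cli.command()
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--patients", default=9, show_default=True, type=int)
@click.option("--fs", default=512.0, show_default=True, type=float)
@click.option("--durations", nargs=3, default=(300.0, 900.0, 300.0),
              show_default=True, type=float,
              help="PRE MTI POST durations in seconds")
def simulate(out_dir, seed, patients, fs, durations):
    """Write a synthetic dataset in the BIDS-EEG-style layout."""
    paths = write_synthetic_dataset(out_dir, seed=seed, n_patients=patients,
                                    durations=tuple(durations), fs=fs)
    click.echo(f"wrote {len(paths)} sessions under {out_dir}")


@cli.command()
@click.option("--data", "data_root", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--clinical", "clinical_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None,
              help="override the config seed")
@click.option("--overwrite", is_flag=True)
def analyze(data_root, out_dir, config_path, clinical_path, seed, overwrite):
    """Run the full analysis pipeline over a dataset."""
    try:
        cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
        if seed is not None:
            cfg.seed = seed
    except Exception as exc:
        click.echo(f"config error: {exc}", err=True)
        sys.exit(4)
    try:
        result = run_pipeline(data_root, out_dir, cfg,
                              clinical_path=clinical_path, overwrite=overwrite)
    except (FileNotFoundError, RuntimeError) as exc:
        click.echo(f"data error: {exc}", err=True)
        sys.exit(3)
    click.echo(f"analyzed {result['n_sessions']} sessions "
               f"(EEG {result['n_eeg']}, ECG {result['n_ecg']}, EMG {result['n_emg']}); "
               f"tables in {out_dir}")


@cli.command()
@click.option("--results", "results_dir", required=True, type=click.Path())
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--figures/--no-figures", default=False, show_default=True)
def report(results_dir, out_dir, figures):
    """Render summary tables (and optional figures) from tidy outputs."""
    results_dir = Path(results_dir)
    tsvs = sorted(results_dir.glob("*.tsv"))
    if not tsvs:
        click.echo(f"no result tables found in {results_dir}", err=True)
        sys.exit(3)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = []
    for path in tsvs:
        df = pd.read_csv(path, sep="\t")
        lines.append(f"== {path.stem} ({len(df)} rows) ==")
        lines.append(df.to_string(index=False, max_rows=40))
        lines.append("")
    text = "\n".join(lines)
    (out / "report.txt").write_text(text)
    click.echo(text)
    if figures:
        _render_figures(results_dir, out)


def _render_figures(results_dir: Path, out: Path) -> None:
    """Figures straight from the tidy tables (no recomputation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    con_path = results_dir / "eeg_contrast.tsv"
    if con_path.exists():
        con = pd.read_csv(con_path, sep="\t")
        for pair, sub in con.groupby("pair"):
            piv = sub.pivot_table(index="band", columns="channel", values="mean_change")
            fig, ax = plt.subplots(figsize=(7, 4))
            vmax = np.nanmax(np.abs(piv.to_numpy())) or 1.0
            im = ax.imshow(piv.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            ax.set_xticks(range(len(piv.columns)), piv.columns)
            ax.set_yticks(range(len(piv.index)), piv.index)
            fig.colorbar(im, ax=ax, label="mean z change")
            ax.set_title(f"EEG band-power change {pair}")
            fig.savefig(out / f"eeg_contrast_{pair}.png", dpi=120)
            plt.close(fig)
    for name in ("hrv", "emg"):
        path = results_dir / f"{name}.tsv"
        if not path.exists():
            continue
        df = pd.read_csv(path, sep="\t")
        feats = df["feature"].unique()
        fig, axes = plt.subplots(1, len(feats), figsize=(2.2 * len(feats), 3),
                                 squeeze=False)
        for ax, feat in zip(axes[0], feats):
            sub = df[df["feature"] == feat]
            data = [sub[sub["period"] == p]["value"].to_numpy()
                    for p in ("PRE", "MTI", "POST")]
            ax.boxplot(data, tick_labels=["PRE", "MTI", "POST"])
            ax.set_title(feat, fontsize=9)
        fig.tight_layout()
        fig.savefig(out / f"{name}_periods.png", dpi=120)
        plt.close(fig)


if __name__ == "__main__":
    cli()
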