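"""Session I/O: BIDS-EEG-style dataset discovery/loading and result tables.

Reads datasets laid out as ``sub-*/ses-*/eeg/*_eeg.vhdr|.edf`` with the
accompanying ``*_events.tsv`` (period onsets/durations) and
``*_channels.tsv`` (channel name/type/units).  Raw files go through
:mod:`mne`; modality resolution uses the channels.tsv ``type`` column
first, then a label prefix heuristic.  Units are normalized to uV for
EEG/EMG and mV for ECG.

The synthetic writer emits the same layout using the BrainVision
format (text .vhdr/.vmrk header plus IEEE-float .eeg), which any BIDS
tool and :func:`load_session` itself can read back.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    InvalidSegmentationError,
    Modality,
    PeriodSegmentation,
    Recording,
    SessionRecord,
)

__all__ = [
    "SessionManifest",
    "discover_sessions",
    "load_session",
    "write_session",
    "write_results",
    "write_synthetic_dataset",
    "EmptyDatasetError",
    "UnsupportedFormatError",
    "ChannelClassificationError",
]


class EmptyDatasetError(FileNotFoundError):
    """No BIDS subjects found under the dataset root."""


class UnsupportedFormatError(ValueError):
    """Raw data format other than EDF(+) or BrainVision."""


class ChannelClassificationError(ValueError):
    """A channel's modality could not be resolved."""


DEFAULT_LABEL_MAP = {"PRE": "PRE", "MTI": "MTI", "POST": "POST"}


@dataclass(frozen=True)
class SessionManifest:
    root: Path
    subject: str          # e.g. "sub-01"
    session: str          # e.g. "ses-01"
    eeg_path: Path        # raw data header (.vhdr or .edf)
    events_path: Path
    channels_path: Path | None

    def __post_init__(self):
        for p in (self.eeg_path, self.events_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def discover_sessions(root) -> list[SessionManifest]:
    """One manifest per sub-*/ses-* pair holding an EEG raw file.

    Deterministic lexicographic ordering by subject then session.
    Non-BIDS folder names are ignored.
    """
    root = Path(root)
    if not root.is_dir():
        raise NotADirectoryError(root)
    manifests = []
    for sub in sorted(root.glob("sub-*")):
        if not sub.is_dir():
            continue
        for ses in sorted(sub.glob("ses-*")):
            eeg_dir = ses / "eeg"
            if not eeg_dir.is_dir():
                continue
            raws = sorted(eeg_dir.glob("*_eeg.vhdr")) + sorted(eeg_dir.glob("*_eeg.edf"))
            if not raws:
                continue
            raw = raws[0]
            stem = raw.name.rsplit("_eeg.", 1)[0]
            events = eeg_dir / f"{stem}_events.tsv"
            channels = eeg_dir / f"{stem}_channels.tsv"
            manifests.append(SessionManifest(
                root=root, subject=sub.name, session=ses.name,
                eeg_path=raw, events_path=events,
                channels_path=channels if channels.exists() else None,
            ))
    if not manifests:
        raise EmptyDatasetError(f"no sub-*/ses-*/eeg sessions under {root}")
    return manifests


def _resolve_modality(name: str, type_map: dict[str, str]) -> Modality:
    t = type_map.get(name, "").upper()
    if t in ("EEG", "ECG", "EMG"):
        return Modality(t)
    upper = name.upper()
    for prefix in ("ECG", "EKG"):
        if upper.startswith(prefix):
            return Modality.ECG
    if upper.startswith("EMG"):
        return Modality.EMG
    if t == "":
        raise ChannelClassificationError(
            f"cannot resolve modality of channel {name!r} (no type, no known prefix)"
        )
    raise ChannelClassificationError(f"unknown channel type {t!r} for {name!r}")


def load_session(
    manifest: SessionManifest, label_map: dict[str, str] | None = None,
) -> SessionRecord:
    """Load one session into per-modality Recordings plus its segmentation."""
    import mne

    path = Path(manifest.eeg_path)
    if path.suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise UnsupportedFormatError(f"unsupported raw format: {path.suffix}")
    fs = float(raw.info["sfreq"])
    data_v = raw.get_data()  # Volts
    names = list(raw.ch_names)

    type_map: dict[str, str] = {}
    if manifest.channels_path is not None:
        ch_tab = pd.read_csv(manifest.channels_path, sep="\t")
        if {"name", "type"}.issubset(ch_tab.columns):
            type_map = dict(zip(ch_tab["name"].astype(str), ch_tab["type"].astype(str)))

    events = pd.read_csv(manifest.events_path, sep="\t")
    label_col = "trial_type" if "trial_type" in events.columns else "value"
    if not {"onset", "duration"}.issubset(events.columns) or label_col not in events.columns:
        raise InvalidSegmentationError(
            f"events table {manifest.events_path} lacks onset/duration/trial_type"
        )
    annotations = tuple(
        (float(r["onset"]), float(r["duration"]), str(r[label_col]))
        for _, r in events.iterrows()
    )
    segmentation = PeriodSegmentation.from_annotations(
        annotations, label_map or DEFAULT_LABEL_MAP)

    groups: dict[Modality, list[int]] = {}
    for i, name in enumerate(names):
        mod = _resolve_modality(name, type_map)
        groups.setdefault(mod, []).append(i)
    recordings: dict[Modality, Recording] = {}
    for mod, idx in groups.items():
        scale = 1e3 if mod is Modality.ECG else 1e6  # V -> mV or uV
        recordings[mod] = Recording(
            modality=mod,
            channel_labels=tuple(names[i] for i in idx),
            sampling_rate=fs,
            data=data_v[idx] * scale,
            annotations=annotations,
        )
    return SessionRecord(
        patient_id=manifest.subject, session=int(manifest.session.split("-")[1]),
        recordings=recordings, segmentation=segmentation,
    )


# ---------------------------------------------------------------------------
# BrainVision + BIDS sidecar writing (synthetic sessions)

def _write_brainvision(base: Path, data_uv: np.ndarray, fs: float,
                       names: list[str]) -> None:
    """Minimal BrainVision writer: multiplexed IEEE float 32, unit uV."""
    vhdr, vmrk, eeg = base.with_suffix(".vhdr"), base.with_suffix(".vmrk"), base.with_suffix(".eeg")
    n_ch = data_uv.shape[0]
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "BrainVision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg.name}\n\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,0\n",
        encoding="utf-8",
    )
    data_uv.T.astype("<f4").tofile(eeg)


def write_session(
    out_root,
    subject: str,
    session: int,
    recordings: dict,
    segmentation: PeriodSegmentation,
    task: str = "mar",
    ground_truth: dict | None = None,
) -> Path:
    """Write one session in the BIDS-EEG-style layout (BrainVision raw).

    All modalities must share one sampling rate (they are multiplexed
    into a single raw file, as in the acquisition hardware).  ECG data
    (mV) is stored as uV in the raw file and converted back on load.
    """
    out_root = Path(out_root)
    fss = {rec.sampling_rate for rec in recordings.values()}
    if len(fss) != 1:
        raise ValueError("all modalities in one raw file must share one sampling rate")
    fs = fss.pop()
    names, rows, types = [], [], []
    for mod in (Modality.EEG, Modality.ECG, Modality.EMG):
        rec = recordings.get(mod) or recordings.get(mod.value)
        if rec is None:
            continue
        scale = 1e3 if mod is Modality.ECG else 1.0  # mV -> uV for storage
        for c, label in enumerate(rec.channel_labels):
            names.append(label)
            rows.append(rec.data[c] * scale)
            types.append(mod.value)
    eeg_dir = out_root / subject / f"ses-{session:02d}" / "eeg"
    eeg_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{subject}_ses-{session:02d}_task-{task}"
    _write_brainvision(eeg_dir / f"{stem}_eeg", np.vstack(rows), fs, names)
    pd.DataFrame({
        "name": names, "type": types,
        "units": ["µV"] * len(names),
        "sampling_frequency": [fs] * len(names),
    }).to_csv(eeg_dir / f"{stem}_channels.tsv", sep="\t", index=False)
    ev = pd.DataFrame({
        "onset": [segmentation[p][0] for p in ("PRE", "MTI", "POST")],
        "duration": [segmentation[p][1] - segmentation[p][0]
                     for p in ("PRE", "MTI", "POST")],
        "trial_type": ["PRE", "MTI", "POST"],
    })
    ev.to_csv(eeg_dir / f"{stem}_events.tsv", sep="\t", index=False)
    if ground_truth is not None:
        with open(eeg_dir / f"{stem}_groundtruth.json", "w") as fh:
            json.dump(ground_truth, fh, default=_json_default, indent=1)
    return eeg_dir


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def write_synthetic_dataset(
    out_root,
    seed: int = 0,
    n_patients: int = 9,
    durations=(300.0, 900.0, 300.0),
    fs: float = 512.0,
    profiles: dict | None = None,
    ecg_noise_sd: float = 0.05,
    study_availability: bool = True,
) -> list[Path]:
    """Write a full synthetic dataset in the layout the readers consume.

    With ``study_availability`` the modality availability mirrors the
    study: one patient with a single session (17 sessions), one session
    without ECG (lead disconnection), two sessions without an EMG
    channel, and one session sampled at 256 Hz (EMG ineligible).
    """
    from .synth import (gen_ecg_session, gen_eeg_session, gen_emg_session,
                        study_effect_profiles)

    profiles = profiles or study_effect_profiles()
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    (out_root / "dataset_description.json").write_text(json.dumps({
        "Name": "synthetic music-therapy sessions", "BIDSVersion": "1.8.0",
        "GeneratedBy": [{"Name": "therasig.synth", "seed": seed}],
    }, indent=1))
    sessions = []
    for p in range(1, n_patients + 1):
        n_ses = 1 if (study_availability and p == n_patients) else 2
        for s in range(1, n_ses + 1):
            sessions.append((p, s))
    # availability pattern over the session list
    no_ecg = {sessions[2]} if study_availability and len(sessions) > 2 else set()
    no_emg = set(sessions[4:6]) if study_availability else set()
    low_fs = {sessions[6]} if study_availability and len(sessions) > 6 else set()
    written = []
    for i, (p, s) in enumerate(sessions):
        fs_this = 256.0 if (p, s) in low_fs else fs
        sess_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        eeg, seg = gen_eeg_session(profiles["eeg"], durations, fs_this,
                                   seed=sess_seed)
        recordings = {Modality.EEG: eeg}
        truth: dict = {"seed": sess_seed}
        if (p, s) not in no_ecg:
            ecg, _, peaks = gen_ecg_session(profiles["autonomic"], durations,
                                            fs_this, seed=sess_seed + 1,
                                            noise_sd=ecg_noise_sd)
            recordings[Modality.ECG] = ecg
            truth["r_peak_times"] = peaks
        if (p, s) not in no_emg and fs_this >= 512:
            emg, _, = gen_emg_session(profiles["emg"], durations, fs_this,
                                      seed=sess_seed + 2)
            recordings[Modality.EMG] = emg
        elif (p, s) in low_fs:
            # EMG acquired but ineligible for frequency analysis: plain noise
            rng = np.random.default_rng(sess_seed + 2)
            durs = (durations if isinstance(durations, dict)
                    else dict(zip(("PRE", "MTI", "POST"), durations)))
            n = int(round(sum(float(v) for v in durs.values()) * fs_this))
            emg = Recording(Modality.EMG, ("EMG",), fs_this,
                            rng.standard_normal((1, n)) * 5.0)
            recordings[Modality.EMG] = emg
        written.append(write_session(out_root, f"sub-{p:02d}", s, recordings, seg,
                                     ground_truth=truth))
    return written


# ---------------------------------------------------------------------------
# result tables

def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir,
    seed: int | None = None,
    config: dict | None = None,
    overwrite: bool = False,
) -> dict[str, Path]:
    """One TSV per named table plus a JSON run summary.

    TSVs use '.' decimals, UTF-8, Unix newlines, and full-precision
    (shortest round-trip) float rendering, so a write->read round trip
    preserves every numeric exactly and reruns diff byte-identically.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True)")
        table.to_csv(path, sep="\t", index=False, lineterminator="\n",
                     encoding="utf-8")
        paths[name] = path
    cfg_json = json.dumps(config or {}, sort_keys=True, default=_json_default)
    summary = {
        "software": "therasig",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "config": config or {},
        "tables": sorted(tables),
    }
    spath = out_dir / "run_summary.json"
    if spath.exists() and not overwrite:
        raise FileExistsError(f"{spath} exists (pass overwrite=True)")
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)
    paths["run_summary"] = spath
    return paths
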