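"""Readers, writers, run configuration and the end-to-end orchestrator.

File dialects are deliberately plain: BIDS-style tab-separated events files
(onset/duration in seconds, dot decimals), wide CSV intensity matrices with
a JSON sidecar carrying sampling metadata, long-format CSV for preprocessed
series, and YAML for run configuration. SNIRF import/export is available
when h5py is installed (``HAS_SNIRF``).

A single top-level seed deterministically derives every per-stage and
per-session sub-seed, so rerunning any stage or the whole pipeline with the
same configuration reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import energy as energy_mod
from .preprocess import FilterSpec, HemoSeries, MbllParams, WaveletSpec, preprocess_pipeline
from .protocol import (Event, EventTimeline, ProtocolConfig, StimulusPool,
                       assign_stimuli, build_programme)
from .simulate import (HRFParams, LearningProfile, Montage, NoiseParams,
                       RawRecording, simulate_session)

try:
    import h5py
    HAS_SNIRF = True
except ImportError:  # pragma: no cover
    HAS_SNIRF = False

__all__ = [
    "HAS_SNIRF", "RunConfig", "read_events", "write_events",
    "read_recording", "write_recording", "write_hemo", "read_hemo",
    "write_snirf", "read_snirf", "run_all", "derive_seed",
]

_VALID_TRIAL_TYPES = {"baseline", "contextualisation", "induction_prompt",
                      "regulation_prompt"}


def derive_seed(seed: int, *key: int) -> int:
    """Deterministic sub-seed derivation (stable across platforms, < 2**31)."""
    h = hashlib.sha256(("/".join(str(k) for k in (seed, *key))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


# ---------------------------------------------------------------- events.tsv

def write_events(timeline: EventTimeline, path: str | Path) -> None:
    """Write a BIDS-style events.tsv (onset, duration, trial_type, block, stim_id)."""
    rows = [{"onset": ev.onset, "duration": ev.duration,
             "trial_type": ev.event_type,
             "block": "" if ev.block_index is None else ev.block_index,
             "stim_id": ev.stim_id or ""} for ev in timeline.events]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def _parse_number(raw: str, column: str, row: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row}: non-numeric {column} {raw!r} (dot-decimal seconds "
            "required)") from None


def read_events(path: str | Path, session_index: int = 1,
                stage: str = "Adaptation") -> EventTimeline:
    """Read and validate a BIDS-style events.tsv into an EventTimeline."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: no events")
    missing = {"onset", "duration", "trial_type"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    events = []
    for i, rec in enumerate(df.to_dict("records"), start=2):  # header is row 1
        ttype = rec["trial_type"]
        if ttype not in _VALID_TRIAL_TYPES:
            raise ValueError(f"row {i}: unknown trial_type {ttype!r}")
        block = rec.get("block", "")
        stim = rec.get("stim_id", "")
        events.append(Event(
            onset=_parse_number(rec["onset"], "onset", i),
            duration=_parse_number(rec["duration"], "duration", i),
            event_type=ttype,
            block_index=int(block) if block not in ("", None) else None,
            stim_id=stim or None,
        ))
    total = max(ev.onset + ev.duration for ev in events)
    return EventTimeline(session_index=session_index, stage=stage,
                         events=tuple(events), total_duration=total)


# ------------------------------------------------------- recording CSV + JSON

def write_recording(recording: RawRecording, out_dir: str | Path,
                    stem: str = "recording") -> dict[str, Path]:
    """Write intensity wide CSV, ground-truth CSV, events.tsv and JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = recording.times
    cols = {"time_s": t}
    for i, lab in enumerate(recording.montage.labels):
        for w, wl in enumerate(recording.wavelengths):
            cols[f"{lab}_{int(wl)}"] = recording.intensity[i, w]
    intensity_path = out_dir / f"{stem}_intensity.csv"
    pd.DataFrame(cols).to_csv(intensity_path, index=False, float_format="%.10g")

    paths = {"intensity": intensity_path}
    if recording.ground_truth is not None:
        gcols = {"time_s": t}
        for i, lab in enumerate(recording.montage.labels):
            for c, chrom in enumerate(("hbo", "hbr")):
                gcols[f"{lab}_{chrom}"] = recording.ground_truth[i, c]
        gt_path = out_dir / f"{stem}_ground_truth.csv"
        pd.DataFrame(gcols).to_csv(gt_path, index=False, float_format="%.10g")
        paths["ground_truth"] = gt_path

    events_path = out_dir / f"{stem}_events.tsv"
    write_events(recording.timeline, events_path)
    paths["events"] = events_path

    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "wavelengths": list(recording.wavelengths),
        "pad_pre": recording.pad_pre,
        "pad_post": recording.pad_post,
        "seed": recording.seed,
        "session_index": recording.timeline.session_index,
        "stage": recording.timeline.stage,
        "montage": {
            "n_sources": recording.montage.n_sources,
            "n_detectors": recording.montage.n_detectors,
            "channels": [list(ch) for ch in recording.montage.channels],
        },
    }
    sidecar_path = out_dir / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    paths["sidecar"] = sidecar_path
    return paths


def read_recording(out_dir: str | Path, stem: str = "recording") -> RawRecording:
    """Read a recording written by :func:`write_recording`."""
    out_dir = Path(out_dir)
    sidecar_path = out_dir / f"{stem}.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"{sidecar_path} missing: regenerate the recording (the sidecar "
            "carries required sampling metadata)")
    meta = json.loads(sidecar_path.read_text())
    montage = Montage(
        channels=tuple((int(s), int(d), float(sep), str(reg))
                       for s, d, sep, reg in meta["montage"]["channels"]),
        n_sources=meta["montage"]["n_sources"],
        n_detectors=meta["montage"]["n_detectors"])
    timeline = read_events(out_dir / f"{stem}_events.tsv",
                           session_index=meta["session_index"], stage=meta["stage"])
    df = pd.read_csv(out_dir / f"{stem}_intensity.csv")
    fs = meta["sampling_rate"]
    n = len(df)
    n_expected = int(round((timeline.total_duration + meta["pad_pre"]
                            + meta["pad_post"]) * fs))
    if abs(n - n_expected) > 1:
        raise ValueError(
            f"sidecar sampling_rate {fs} Hz inconsistent with {n} samples over "
            f"{timeline.total_duration} s (+padding): expected ~{n_expected}")
    wavelengths = tuple(meta["wavelengths"])
    intensity = np.empty((len(montage.channels), 2, n))
    for i, lab in enumerate(montage.labels):
        for w, wl in enumerate(wavelengths):
            intensity[i, w] = df[f"{lab}_{int(wl)}"].to_numpy()
    gt_path = out_dir / f"{stem}_ground_truth.csv"
    ground_truth = None
    if gt_path.exists():
        gdf = pd.read_csv(gt_path)
        ground_truth = np.empty((len(montage.channels), 2, n))
        for i, lab in enumerate(montage.labels):
            for c, chrom in enumerate(("hbo", "hbr")):
                ground_truth[i, c] = gdf[f"{lab}_{chrom}"].to_numpy()
    return RawRecording(sampling_rate=fs, intensity=intensity, montage=montage,
                        timeline=timeline, ground_truth=ground_truth,
                        wavelengths=wavelengths, pad_pre=meta["pad_pre"],
                        pad_post=meta["pad_post"], seed=meta["seed"])


# -------------------------------------------------------------- hemo series

def write_hemo(hemo: HemoSeries, out_dir: str | Path, stem: str = "hemo") -> Path:
    """Long-format CSV (channel, chromophore, time_s, value) + provenance JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = hemo.hbo.shape[-1]
    t = np.arange(n) / hemo.sampling_rate
    frames = []
    for chrom, arr in (("hbo", hemo.hbo), ("hbr", hemo.hbr)):
        for i, ch in enumerate(hemo.channels):
            frames.append(pd.DataFrame({"channel": ch, "chromophore": chrom,
                                        "time_s": t, "value": arr[i]}))
    path = out_dir / f"{stem}.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10g")
    prov = {"sampling_rate": hemo.sampling_rate, "channels": hemo.channels,
            "provenance": hemo.provenance, "qc": hemo.qc}
    (out_dir / f"{stem}_provenance.json").write_text(
        json.dumps(prov, indent=1, sort_keys=True))
    return path


def read_hemo(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -------------------------------------------------------------------- SNIRF

def write_snirf(recording: RawRecording, path: str | Path) -> None:
    """Minimal SNIRF (HDF5) export of the raw intensity recording."""
    if not HAS_SNIRF:
        raise RuntimeError("SNIRF support requires h5py")
    n_ch = len(recording.montage.channels)
    t = recording.times
    data = np.concatenate([recording.intensity[:, w, :].T for w in range(2)], axis=1)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=t)
        for j in range(2 * n_ch):
            w, c = divmod(j, n_ch)
            ml = d1.create_group(f"measurementList{j + 1}")
            s, d, _, _ = recording.montage.channels[c]
            ml.create_dataset("sourceIndex", data=s)
            ml.create_dataset("detectorIndex", data=d)
            ml.create_dataset("wavelengthIndex", data=w + 1)
            ml.create_dataset("dataType", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.wavelengths))
        stim_types = {}
        for ev in recording.timeline.events:
            stim_types.setdefault(ev.event_type, []).append(
                [ev.onset, ev.duration, 1.0])
        for k, (name, rows) in enumerate(sorted(stim_types.items()), start=1):
            st = nirs.create_group(f"stim{k}")
            st.create_dataset("name", data=name)
            st.create_dataset("data", data=np.asarray(rows))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SamplingRate", data=recording.sampling_rate)


def read_snirf(path: str | Path, montage: Montage,
               timeline: EventTimeline) -> RawRecording:
    """Re-import intensities from a SNIRF file written by :func:`write_snirf`."""
    if not HAS_SNIRF:
        raise RuntimeError("SNIRF support requires h5py")
    with h5py.File(path, "r") as f:
        data = f["nirs/data1/dataTimeSeries"][()]
        fs = float(f["nirs/metaDataTags/SamplingRate"][()])
        wavelengths = tuple(f["nirs/probe/wavelengths"][()])
    n_ch = len(montage.channels)
    n = data.shape[0]
    intensity = np.empty((n_ch, 2, n))
    for w in range(2):
        intensity[:, w, :] = data[:, w * n_ch:(w + 1) * n_ch].T
    return RawRecording(sampling_rate=fs, intensity=intensity, montage=montage,
                        timeline=timeline, wavelengths=wavelengths)


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Serializable configuration of an end-to-end run."""

    seed: int = 0
    out_dir: str = "mpa_nfdk_run"
    n_sessions: int = 4
    channels: list[str] | None = None
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    hrf: HRFParams = field(default_factory=HRFParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    learning: str = "default"            # "default" or "flat"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    wavelet_spec: WaveletSpec = field(default_factory=WaveletSpec)
    mbll: MbllParams = field(default_factory=MbllParams)
    epoch_duration: float = 15.0
    sampling_rate: float = 10.2

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, frozenset)):
                return [enc(v) for v in sorted(obj)] if isinstance(obj, frozenset) \
                    else [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj
        return enc(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "protocol" in d and isinstance(d["protocol"], dict):
            p = dict(d["protocol"])
            if p.get("stage_map"):
                p["stage_map"] = {int(k): v for k, v in p["stage_map"].items()}
            d["protocol"] = ProtocolConfig(**p)
        if "hrf" in d and isinstance(d["hrf"], dict):
            d["hrf"] = HRFParams(**d["hrf"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseParams(**d["noise"])
        if "filter_spec" in d and isinstance(d["filter_spec"], dict):
            fs = dict(d["filter_spec"])
            fs["band"] = tuple(fs["band"])
            d["filter_spec"] = FilterSpec(**fs)
        if "wavelet_spec" in d and isinstance(d["wavelet_spec"], dict):
            ws = dict(d["wavelet_spec"])
            ws["removed_details"] = frozenset(ws["removed_details"])
            d["wavelet_spec"] = WaveletSpec(**ws)
        if "mbll" in d and isinstance(d["mbll"], dict):
            m = dict(d["mbll"])
            from .simulate import ExtinctionSpec
            if "extinction" in m and isinstance(m["extinction"], dict):
                m["extinction"] = ExtinctionSpec(
                    matrix=tuple(tuple(r) for r in m["extinction"]["matrix"]))
            m["dpf"] = tuple(m["dpf"])
            d["mbll"] = MbllParams(**m)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """schedule -> simulate -> preprocess -> analyze, with a hash manifest.

    Returns the manifest: per-stage artifact paths and content hashes.
    Identical (config, seed) reproduces identical hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    # schedule
    timelines = build_programme(config.protocol, config.n_sessions)
    pool = StimulusPool.default(config.protocol,
                                rng_seed=derive_seed(config.seed, 1))
    timelines = assign_stimuli(config.protocol, pool, timelines)
    sched_dir = out / "schedule"
    sched_dir.mkdir(exist_ok=True)
    sched_paths = []
    for tl in timelines:
        p = sched_dir / f"session-{tl.session_index:02d}_events.tsv"
        write_events(tl, p)
        sched_paths.append(p)
    manifest["stages"]["schedule"] = {str(p): _sha256(p) for p in sched_paths}

    # simulate + preprocess + epoch
    montage = Montage.default()
    if config.channels:
        montage = montage.subset(config.channels)
    learning = (LearningProfile.default() if config.learning == "default"
                else LearningProfile.flat()).subset(montage.labels)
    sim_dir = out / "simulate"
    hemo_dir = out / "preprocess"
    sim_hashes, hemo_hashes = {}, {}
    hemo_list = []
    for tl in timelines:
        rec = simulate_session(
            config.protocol, tl.session_index, montage, config.hrf,
            dataclasses.replace(config.noise,
                                rng_seed=derive_seed(config.seed, 2, tl.session_index)),
            learning, config.sampling_rate,
            seed=derive_seed(config.seed, 2, tl.session_index))
        rec = dataclasses.replace(rec, timeline=tl)  # carry stimulus ids
        paths = write_recording(rec, sim_dir, stem=f"session-{tl.session_index:02d}")
        sim_hashes.update({str(p): _sha256(p) for p in paths.values()})
        hemo = preprocess_pipeline(rec, config.filter_spec, config.wavelet_spec,
                                   config.mbll)
        hp = write_hemo(hemo, hemo_dir, stem=f"session-{tl.session_index:02d}")
        ep = hemo_dir / f"session-{tl.session_index:02d}_events.tsv"
        write_events(tl, ep)
        hemo_hashes.update({str(hp): _sha256(hp), str(ep): _sha256(ep)})
        hemo_list.append(hemo)
    manifest["stages"]["simulate"] = sim_hashes
    manifest["stages"]["preprocess"] = hemo_hashes

    # analyze
    records = energy_mod.analyze_programme(hemo_list, config.epoch_duration)
    ana_dir = out / "analyze"
    ana_dir.mkdir(exist_ok=True)
    rec_path = ana_dir / "energy_ratios.csv"
    records.to_csv(rec_path, index=False, float_format="%.10g")
    summary = energy_mod.summarize_sessions(records)
    sum_path = ana_dir / "session_summary.csv"
    summary.to_csv(sum_path, index=False, float_format="%.10g")
    manifest["stages"]["analyze"] = {str(p): _sha256(p)
                                     for p in (rec_path, sum_path)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
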