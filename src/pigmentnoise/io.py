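"""Delimited-text readers and writers for traces, spectra and time courses.

All formats are two- or three-column delimited text (TSV written by default;
comma or tab accepted on read) with a mandatory header naming the columns and
their units, e.g. ``time_s<TAB>current_pA``.  Parse errors name the offending
line.  Write-then-read round-trips are value-exact to float repr precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CurrentTrace, EventList, FlashEnsemble, SinglePhotonResponse
from .errors import DataError
from .events import integration_time
from .spectra import AbsorbanceSpectrum, ExchangeTimeCourse

TRACE_COLUMNS = ("time_s", "current_pA")
SPECTRUM_COLUMNS = ("wavelength_nm", "od")
TIMECOURSE_COLUMNS = ("time_min", "fraction_9cis", "sd")


def _read_table(path: str | Path, expected: tuple[str, ...], n_required: int) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: file not found")
    try:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if first.count("\t") >= first.count(",") else ","
        df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise DataError(f"{path}: could not parse delimited text: {exc}") from exc
    cols = [str(c).strip() for c in df.columns]
    if len(cols) < n_required or cols[:n_required] != list(expected[:n_required]):
        raise DataError(
            f"{path}: expected header columns {expected[:n_required]}, got {tuple(cols)}; "
            "the first line must name the columns and units"
        )
    df.columns = cols
    for col in cols[: max(n_required, min(len(cols), len(expected)))]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise DataError(f"{path}:{line}: non-numeric value in column {col!r}")
        if df[col].isna().any():
            line = int(np.flatnonzero(df[col].isna())[0]) + 2
            raise DataError(f"{path}:{line}: missing value in column {col!r}")
        df[col] = pd.to_numeric(df[col])
    return df


def _check_increasing(values: np.ndarray, name: str, path: str | Path) -> None:
    diffs = np.diff(values)
    if (diffs <= 0).any():
        line = int(np.flatnonzero(diffs <= 0)[0]) + 3  # header + 1-based + next row
        raise DataError(f"{path}:{line}: {name} must be strictly increasing")


def read_trace(path: str | Path, filter_cutoff: float = 20.0) -> CurrentTrace:
    """Read a (time_s, current_pA) trace; the sampling rate is inferred from
    the (required uniform) time spacing."""
    df = _read_table(path, TRACE_COLUMNS, 2)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: trace needs at least two samples")
    _check_increasing(t, "time_s", path)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        line = int(np.argmax(np.abs(dt - dt[0]))) + 3
        raise DataError(f"{path}:{line}: time axis is not uniformly sampled")
    return CurrentTrace(
        df["current_pA"].to_numpy(dtype=float),
        sampling_rate=1.0 / dt[0],
        filter_cutoff=filter_cutoff,
    )


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "current_pA": trace.samples}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_spr(path: str | Path) -> SinglePhotonResponse:
    """Read a single-photon response waveform stored as a trace file; the
    quantal amplitude is the waveform peak."""
    trace = read_trace(path)
    w = trace.samples
    if not np.any(w > 0):
        raise DataError(f"{path}: single-photon waveform has no positive peak")
    return SinglePhotonResponse(
        waveform=w,
        sampling_rate=trace.sampling_rate,
        amplitude=float(w.max()),
        integration_time=integration_time(w, trace.sampling_rate),
        peak_time=float(np.argmax(w)) / trace.sampling_rate,
    )


def write_spr(spr: SinglePhotonResponse, path: str | Path) -> None:
    write_trace(CurrentTrace(spr.waveform, spr.sampling_rate), path)


def read_spectrum(path: str | Path) -> AbsorbanceSpectrum:
    df = _read_table(path, SPECTRUM_COLUMNS, 2)
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    _check_increasing(wl, "wavelength_nm", path)
    return AbsorbanceSpectrum(wl, df["od"].to_numpy(dtype=float))


def write_spectrum(spectrum: AbsorbanceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "od": spectrum.od}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timecourse(path: str | Path) -> ExchangeTimeCourse:
    df = _read_table(path, TIMECOURSE_COLUMNS, 2)
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    return ExchangeTimeCourse(
        times=df["time_min"].to_numpy(dtype=float),
        fraction_9cis=df["fraction_9cis"].to_numpy(dtype=float),
        sd=sd,
    )


def write_timecourse(tc: ExchangeTimeCourse, path: str | Path) -> None:
    data = {"time_min": tc.times, "fraction_9cis": tc.fraction_9cis}
    if tc.sd is not None:
        data["sd"] = tc.sd
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ensemble(manifest_path: str | Path) -> FlashEnsemble:
    """Read a flash ensemble from a JSON manifest.

    The manifest holds ``flash_intensity`` (photons µm^-2), ``flash_time``
    (s) and ``trials``: a list of trace files relative to the manifest.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"{manifest_path}: unreadable manifest: {exc}") from exc
    for key in ("flash_intensity", "flash_time", "trials"):
        if key not in manifest:
            raise DataError(f"{manifest_path}: manifest missing key {key!r}")
    trials = [read_trace(manifest_path.parent / p) for p in manifest["trials"]]
    return FlashEnsemble(
        trials=trials,
        flash_intensity=float(manifest["flash_intensity"]),
        flash_time=float(manifest["flash_time"]),
    )


def write_ensemble(ensemble: FlashEnsemble, directory: str | Path, stem: str = "trial") -> Path:
    """Write each trial as a trace file plus a JSON manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, trial in enumerate(ensemble.trials):
        name = f"{stem}_{i:03d}.tsv"
        write_trace(trial, directory / name)
        names.append(name)
    manifest = {
        "flash_intensity": ensemble.flash_intensity,
        "flash_time": ensemble.flash_time,
        "trials": names,
    }
    out = directory / f"{stem}_manifest.json"
    out.write_text(json.dumps(manifest, indent=2))
    return out


EVENT_COLUMNS = ("time_s", "amplitude_pA", "integration_time_s")


def read_events(path: str | Path, duration: float) -> "EventList":
    """Read a detected-event table; ``duration`` is the parent recording
    length in seconds (events must lie within it)."""
    df = _read_table(path, EVENT_COLUMNS, 1)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size:
        _check_increasing(t, "time_s", path)
    amp = df["amplitude_pA"].to_numpy(dtype=float) if "amplitude_pA" in df.columns else np.full(t.size, np.nan)
    ti = df["integration_time_s"].to_numpy(dtype=float) if "integration_time_s" in df.columns else np.full(t.size, np.nan)
    return EventList(times=t, amplitudes=amp, integration_times=ti, duration=duration)


def write_events(events: "EventList", path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": events.times,
            "amplitude_pA": events.amplitudes,
            "integration_time_s": events.integration_times,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
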