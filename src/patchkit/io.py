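"""Readers and writers for the plain-text/raw formats the pipeline uses.

Formats:
  trace CSV        time_s,current_pA
  raw trace        little-endian float32 samples + JSON sidecar
                   {sampling_rate_hz, units, seed, truth}
  dose–response    ligand,genotype,concentration_uM,replicate,response
  spectrum CSV     wavelength_nm,intensity
  events TSV       state,start_s,duration_s
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import ConcentrationResponse
from .single_channel import DwellEvent, IdealizedRecord
from .spectra import EmissionSpectrum

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_trace_raw", "read_trace_raw",
    "write_dose_response_csv", "read_dose_response_csv",
    "write_spectrum_csv", "read_spectrum_csv",
    "write_events_tsv", "read_events_tsv",
]


def write_trace_csv(path, samples, sampling_rate: float) -> None:
    samples = np.asarray(samples, dtype=float)
    t = np.arange(samples.size) / sampling_rate
    pd.DataFrame({"time_s": t, "current_pA": samples}).to_csv(path, index=False)


def read_trace_csv(path) -> tuple[np.ndarray, float]:
    """Returns (samples, sampling_rate); the rate is inferred from the time column."""
    df = pd.read_csv(path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"trace CSV {path} lacks required column {col!r}")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("trace CSV must contain at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("trace CSV time column is not uniformly sampled")
    return df["current_pA"].to_numpy(dtype=float), float(1.0 / dt[0])


def write_trace_raw(path, samples, sampling_rate: float,
                    seed: int | None = None, truth: dict | None = None) -> None:
    """Raw little-endian float32 samples plus a JSON sidecar at <path>.json."""
    path = Path(path)
    np.asarray(samples, dtype="<f4").tofile(path)
    sidecar = {"sampling_rate_hz": sampling_rate, "units": "pA",
               "seed": seed, "truth": truth}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_trace_raw(path) -> tuple[np.ndarray, float, dict]:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    samples = np.fromfile(path, dtype="<f4").astype(float)
    return samples, float(sidecar["sampling_rate_hz"]), sidecar


def write_dose_response_csv(path, datasets) -> None:
    """Write one or more DoseResponseDataset / ConcentrationResponse objects."""
    rows = []
    for ds in np.atleast_1d(datasets):
        responses = np.atleast_2d(ds.responses)
        for rep in range(responses.shape[0]):
            for c, r in zip(ds.concentrations, responses[rep]):
                rows.append({"ligand": ds.ligand, "genotype": ds.genotype,
                             "concentration_uM": c, "replicate": rep,
                             "response": r})
    pd.DataFrame(rows, columns=["ligand", "genotype", "concentration_uM",
                                "replicate", "response"]).to_csv(path, index=False)


def read_dose_response_csv(path, po_calibrated: bool = True) -> list[ConcentrationResponse]:
    """One ConcentrationResponse per (ligand, genotype) group in the file."""
    df = pd.read_csv(path)
    required = {"ligand", "genotype", "concentration_uM", "replicate", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose-response CSV {path} lacks columns {sorted(missing)}")
    out = []
    for (ligand, genotype), grp in df.groupby(["ligand", "genotype"], sort=True):
        wide = grp.pivot_table(index="replicate", columns="concentration_uM",
                               values="response")
        if wide.isna().any().any():
            raise ValueError(
                f"dose-response CSV {path}: ragged replicates for "
                f"{ligand}/{genotype} (missing responses at some concentrations)"
            )
        out.append(ConcentrationResponse(
            wide.columns.to_numpy(dtype=float), wide.to_numpy(dtype=float),
            ligand=str(ligand), genotype=str(genotype), po_calibrated=po_calibrated,
        ))
    return out


def write_spectrum_csv(path, wavelengths, intensities) -> None:
    pd.DataFrame({"wavelength_nm": np.asarray(wavelengths, dtype=float),
                  "intensity": np.asarray(intensities, dtype=float)}).to_csv(
        path, index=False)


def read_spectrum_csv(path, condition: str = "control", site: str = "") -> EmissionSpectrum:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "intensity"):
        if col not in df.columns:
            raise ValueError(f"spectrum CSV {path} lacks required column {col!r}")
    return EmissionSpectrum(df["wavelength_nm"].to_numpy(dtype=float),
                            df["intensity"].to_numpy(dtype=float),
                            condition=condition, site=site)


def write_events_tsv(path, events) -> None:
    events = list(events)
    pd.DataFrame({
        "state": [e.state for e in events],
        "start_s": [e.start for e in events],
        "duration_s": [e.duration for e in events],
    }).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[DwellEvent]:
    df = pd.read_csv(path, sep="\t")
    for col in ("state", "start_s", "duration_s"):
        if col not in df.columns:
            raise ValueError(f"events TSV {path} lacks required column {col!r}")
    return [DwellEvent(row.state, float(row.start_s), float(row.duration_s))
            for row in df.itertuples()]
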