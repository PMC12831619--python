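"""SNIRF read/write for continuous-wave two-wavelength recordings.

Files follow the SNIRF HDF5 layout: ``/nirs/data1/dataTimeSeries``
(time x measurement), ``time``, one ``measurementList{i}`` group per
measurement (source, detector, wavelength index, dataType 1 = CW
amplitude), ``/nirs/probe`` with wavelengths and optode positions, and
one ``/nirs/stim{i}`` group per condition label. Channel hemisphere and
region labels ride along as string datasets under ``/nirs/probe`` so
the probe layout round-trips losslessly.
"""

from __future__ import annotations

import numpy as np
import h5py
import pandas as pd

from .layout import ProbeLayout
from .recording import Event, RawRecording

_STR = h5py.string_dtype(encoding="utf-8")


def write_recording(rec: RawRecording, path) -> None:
    """Write a recording as a continuous-wave SNIRF file."""
    n_t, n_ch, n_wl = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=_STR)
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        flat = rec.intensity.reshape(n_t, n_ch * n_wl)  # ch-major, wl-minor
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.times())
        for m in range(n_ch * n_wl):
            ch, wl = divmod(m, n_wl)
            g = data.create_group(f"measurementList{m + 1}")
            g.create_dataset("sourceIndex", data=ch + 1)
            g.create_dataset("detectorIndex", data=ch + 1)
            g.create_dataset("wavelengthIndex", data=wl + 1)
            g.create_dataset("dataType", data=1)
            g.create_dataset("dataTypeIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        half = rec.layout.sd_separation / 2.0
        offset = np.array([0.0, half, 0.0])
        probe.create_dataset("sourcePos3D", data=rec.layout.position - offset)
        probe.create_dataset("detectorPos3D", data=rec.layout.position + offset)
        probe.create_dataset(
            "channelHemispheres", data=list(rec.layout.hemisphere), dtype=_STR
        )
        probe.create_dataset(
            "channelRegions", data=list(rec.layout.region), dtype=_STR
        )
        probe.create_dataset("channelIds", data=rec.layout.channel_id)

        labels = {}
        for ev in rec.events:
            labels.setdefault(ev.label, []).append(ev.time)
        for k, (label, onsets) in enumerate(sorted(labels.items())):
            g = nirs.create_group(f"stim{k + 1}")
            g.create_dataset("name", data=label, dtype=_STR)
            rows = np.array([[t, 0.0, 1.0] for t in sorted(onsets)])
            g.create_dataset("data", data=rows)


def read_recording(path) -> RawRecording:
    """Read a continuous-wave SNIRF file written by this package."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        probe = nirs["probe"]
        wavelengths = tuple(np.asarray(probe["wavelengths"]).tolist())
        if len(wavelengths) != 2:
            raise ValueError(
                f"unsupported SNIRF variant: expected 2 wavelengths, got {len(wavelengths)}"
            )
        src = np.asarray(probe["sourcePos3D"])
        det = np.asarray(probe["detectorPos3D"])
        positions = 0.5 * (src + det)
        sep = float(np.linalg.norm(det[0] - src[0]))
        hemi = np.array([s.decode() if isinstance(s, bytes) else s
                         for s in probe["channelHemispheres"][()]], dtype=object)
        region = np.array([s.decode() if isinstance(s, bytes) else s
                           for s in probe["channelRegions"][()]], dtype=object)
        ids = np.asarray(probe["channelIds"], dtype=int)
        layout = ProbeLayout(ids, positions, hemi, region, sd_separation=sep)

        data = nirs["data1"]
        flat = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(time)))
        n_ch = len(ids)
        intensity = flat.reshape(flat.shape[0], n_ch, 2)

        events = []
        for key in sorted(k for k in nirs if k.startswith("stim")):
            g = nirs[key]
            name = g["name"][()]
            label = name.decode() if isinstance(name, bytes) else str(name)
            for row in np.atleast_2d(np.asarray(g["data"])):
                events.append(Event(float(row[0]), label))
        events.sort(key=lambda e: e.time)
    return RawRecording(intensity, fs, events, layout, wavelengths=wavelengths)


def events_to_frame(rec: RawRecording) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.time, e.label) for e in rec.events], columns=["onset", "label"]
    )
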