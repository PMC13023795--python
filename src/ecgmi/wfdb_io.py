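"""Minimal WFDB (PhysioNet) format-16 reader/writer.

Supports exactly what the PTB-style adapter needs: a text ``.hea`` header
plus an interleaved little-endian 16-bit ``.dat`` signal file, single
signal group.  ``read_wfdb_record`` extracts one named lead and converts
ADC units to millivolt via the per-signal gain/baseline; labels come from a
caller-supplied manifest, never from the files.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .types import EcgRecord

__all__ = ["read_wfdb_record", "write_wfdb_record", "read_wfdb_signals"]

_DEFAULT_GAIN = 2000.0  # ADC units per mV


def write_wfdb_record(record: EcgRecord, path: str | Path,
                      gain: float = _DEFAULT_GAIN) -> Path:
    """Write a single-lead record as <path>.hea / <path>.dat (format 16)."""
    path = Path(path)
    name = path.name
    adc = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    checksum = int(adc.astype(np.int64).sum() % 65536)
    header = (
        f"{name} 1 {record.sampling_rate:g} {adc.size}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0]) if adc.size else 0} "
        f"{checksum} 0 {record.lead}\n"
    )
    path.with_suffix(".hea").write_text(header)
    path.with_suffix(".dat").write_bytes(adc.tobytes())
    return path


def read_wfdb_signals(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    """All leads of a format-16 record -> ({lead: mV samples}, fs)."""
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing header file {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    if len(lines) < 1 + n_sig:
        raise ValueError(f"header {hea} declares {n_sig} signals but lists fewer")

    specs = []
    for i, ln in enumerate(lines[1 : 1 + n_sig]):
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB format {fmt!r} (only 16)")
        gain, baseline = _DEFAULT_GAIN, 0.0
        if len(tok) > 2:
            m = re.match(r"([-\d.eE+]+)(?:\(([-\d]+)\))?(?:/.*)?$", tok[2])
            if m:
                gain = float(m.group(1)) or _DEFAULT_GAIN
                baseline = float(m.group(2) or 0)
        lead = tok[-1] if len(tok) > 8 else f"ch{i}"
        specs.append((fname, gain, baseline, lead))

    dat = path.parent / specs[0][0]
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file {dat}")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if n_samples:
        raw = raw[: n_samples * n_sig]
    sig = raw.reshape(-1, n_sig)
    out = {}
    for ch, (_, gain, baseline, lead) in enumerate(specs):
        out[lead] = (sig[:, ch].astype(float) - baseline) / gain
    return out, fs


def read_wfdb_record(path: str | Path, lead: str = "II",
                     label: str = "healthy", record_id: str | None = None) -> EcgRecord:
    """Extract one named lead as an :class:`EcgRecord`.

    The diagnostic label is supplied by the caller (from a manifest); the
    WFDB files carry no class information this package trusts.
    """
    signals, fs = read_wfdb_signals(path)
    if lead not in signals:
        raise KeyError(f"lead {lead!r} not present in {path}; available: {sorted(signals)}")
    return EcgRecord(samples=signals[lead], sampling_rate=fs, label=label,
                     record_id=record_id or Path(path).name, lead=lead)
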