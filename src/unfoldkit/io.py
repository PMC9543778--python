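"""On-disk formats: curve TSV with header sidecar, dataset manifest, tables.

A curve file is UTF-8 text: '#'-prefixed ``key: value`` header lines
(curve_id, speed_nms, temperature_K, cantilever_k_Nm, sampling_rate_Hz,
provenance), a tab-separated column-name line, then three tab-separated
columns time_s / piezo_nm / force_pN with '.' decimal separator.  Values are
written with 12 significant digits so a write -> read round trip is lossless
to 1e-9 relative.  A JSON manifest links curve files to their acquisition
metadata and records provenance (generator config hash + seed, or
"measured").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from unfoldkit.errors import FormatError
from unfoldkit.simulate import ForceExtensionCurve, SimulationTruth

MANDATORY_HEADER_KEYS = (
    "curve_id", "speed_nms", "temperature_K", "cantilever_k_Nm",
    "sampling_rate_Hz", "provenance",
)
_COLUMNS = ("time_s", "piezo_nm", "force_pN")

TRUTH_COLUMNS = ("curve_id", "event_index", "time_s", "force_pN",
                 "lc_before_nm", "lc_after_nm")


@dataclass
class DatasetManifest:
    """Index of a curve collection plus provenance."""

    curves: list  # dicts: path, curve_id, pulling_speed_nms, temperature_K, cantilever_k_Nm
    provenance: dict
    format_version: int = 1
    root: Optional[Path] = None  # directory the relative paths resolve against

    def curve_paths(self) -> list:
        base = self.root or Path(".")
        return [base / entry["path"] for entry in self.curves]


def write_curve(path, curve: ForceExtensionCurve) -> None:
    """Write one curve in the package's TSV format."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# curve_id: {curve.curve_id}\n")
        fh.write(f"# speed_nms: {curve.pulling_speed:.12g}\n")
        fh.write(f"# temperature_K: {curve.temperature:.12g}\n")
        fh.write(f"# cantilever_k_Nm: {curve.cantilever_k:.12g}\n")
        fh.write(f"# sampling_rate_Hz: {curve.sampling_rate:.12g}\n")
        fh.write(f"# provenance: {curve.provenance}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for t, z, f in zip(curve.time, curve.piezo_position, curve.force):
            fh.write(f"{t:.12g}\t{z:.12g}\t{f:.12g}\n")


def read_curve(path) -> ForceExtensionCurve:
    """Read one curve file; raises :class:`FormatError` naming the bad line."""
    path = Path(path)
    headers = {}
    data_rows = []
    with open(path, "r", encoding="utf-8") as fh:  # universal newlines: CRLF ok
        lines = fh.read().splitlines()
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" not in body:
            raise FormatError(f"{path}:{i + 1}: malformed header line {line!r}")
        key, _, value = body.partition(":")
        headers[key.strip()] = value.strip()
    missing = [k for k in MANDATORY_HEADER_KEYS if k not in headers]
    if missing:
        raise FormatError(f"{path}: missing mandatory header key(s): {missing}")
    if i >= len(lines) or tuple(lines[i].split("\t")) != _COLUMNS:
        expected = "\t".join(_COLUMNS)
        raise FormatError(f"{path}:{i + 1}: expected column line {expected!r}")
    for j, line in enumerate(lines[i + 1:], start=i + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{j}: expected 3 tab-separated values")
        try:
            data_rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(f"{path}:{j}: non-numeric value ({exc})") from exc
    if not data_rows:
        raise FormatError(f"{path}: no data rows")
    arr = np.asarray(data_rows, dtype=float)
    time = arr[:, 0]
    if np.any(np.diff(time) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    try:
        return ForceExtensionCurve(
            time=time,
            piezo_position=arr[:, 1],
            force=arr[:, 2],
            pulling_speed=float(headers["speed_nms"]),
            temperature=float(headers["temperature_K"]),
            cantilever_k=float(headers["cantilever_k_Nm"]),
            sampling_rate=float(headers["sampling_rate_Hz"]),
            curve_id=headers["curve_id"],
            provenance=headers["provenance"],
        )
    except ValueError as exc:
        raise FormatError(f"{path}: invalid header value ({exc})") from exc


def write_truth_csv(path, truths) -> None:
    """Ground-truth event log as CSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TRUTH_COLUMNS) + "\n")
        for truth in truths:
            for ev in truth.events:
                fh.write(
                    f"{truth.curve_id},{ev.event_index},{ev.time:.12g},"
                    f"{ev.force:.12g},{ev.lc_before:.12g},{ev.lc_after:.12g}\n"
                )


def write_manifest(path, manifest: DatasetManifest) -> None:
    payload = {
        "format_version": manifest.format_version,
        "provenance": manifest.provenance,
        "curves": manifest.curves,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> DatasetManifest:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    for key in ("format_version", "provenance", "curves"):
        if key not in payload:
            raise FormatError(f"{path}: manifest missing '{key}'")
    manifest = DatasetManifest(
        curves=payload["curves"],
        provenance=payload["provenance"],
        format_version=payload["format_version"],
        root=path.parent,
    )
    ids = [c["curve_id"] for c in manifest.curves]
    if len(ids) != len(set(ids)):
        raise FormatError(f"{path}: duplicate curve_ids in manifest")
    for p in manifest.curve_paths():
        if not Path(p).exists():
            raise FormatError(f"{path}: referenced curve file missing: {p}")
    return manifest


def write_dataset(outdir, curves, truths, provenance: dict) -> DatasetManifest:
    """Write curves + truth log + manifest into ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for curve in curves:
        fname = f"{curve.curve_id}.tsv"
        write_curve(outdir / fname, curve)
        entries.append({
            "path": fname,
            "curve_id": curve.curve_id,
            "pulling_speed_nms": curve.pulling_speed,
            "temperature_K": curve.temperature,
            "cantilever_k_Nm": curve.cantilever_k,
        })
    write_truth_csv(outdir / "truth.csv", truths)
    manifest = DatasetManifest(curves=entries, provenance=provenance, root=outdir)
    write_manifest(outdir / "manifest.json", manifest)
    return manifest
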