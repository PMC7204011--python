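"""Serialization: sparse dot-plot text format, PNG rasters, run manifests.

The dot-plot text format is line-oriented and diff-friendly:

    #n=<int> window=<int> black_point=<int>
    #members=<comma-separated ids>          (optional, consensus plots)
    <i>\t<j>
    ...

with 0-based strictly-upper-triangle pixel coordinates, sorted.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
import platform

import numpy as np

from .fingerprint import DotPlot


class DotPlotFormatError(ValueError):
    """A dot-plot file violates the sparse text format or its invariants."""


def write_dotplot(plot: DotPlot, path: str | os.PathLike, members: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n={plot.n} window={plot.window} black_point={plot.black_point}\n")
        if members:
            fh.write("#members=" + ",".join(members) + "\n")
        for i, j in plot.pixels:
            fh.write(f"{i}\t{j}\n")


def read_dotplot(path: str | os.PathLike) -> DotPlot:
    """Read a sparse dot-plot file, enforcing the upper-triangle invariants."""
    header: dict[str, int] | None = None
    pixels: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#members="):
                continue
            if line.startswith("#"):
                try:
                    header = dict(
                        (k, int(v))
                        for k, v in (item.split("=") for item in line[1:].split())
                    )
                except ValueError:
                    raise DotPlotFormatError(f"{path}:{lineno}: malformed header") from None
                continue
            if header is None:
                raise DotPlotFormatError(f"{path}:{lineno}: pixel data before header")
            try:
                i, j = (int(x) for x in line.split("\t"))
            except ValueError:
                raise DotPlotFormatError(f"{path}:{lineno}: malformed pixel line {line!r}") from None
            if i >= j:
                raise DotPlotFormatError(
                    f"{path}:{lineno}: pixel ({i},{j}) not strictly upper-triangle"
                )
            if i < 0 or j >= header["n"]:
                raise DotPlotFormatError(f"{path}:{lineno}: pixel ({i},{j}) out of range")
            pixels.append((i, j))
    if header is None:
        raise DotPlotFormatError(f"{path}: missing header line")
    for key in ("n", "window", "black_point"):
        if key not in header:
            raise DotPlotFormatError(f"{path}: header lacks {key!r}")
    return DotPlot(
        n=header["n"],
        window=header["window"],
        black_point=header["black_point"],
        pixels=np.array(pixels, dtype=np.int64).reshape(-1, 2),
    )


def export_png(plot: DotPlot, path: str | os.PathLike, scale: int = 1) -> None:
    """Render the fingerprint (mirrored symmetric, white-on-black pixels
    shown black-on-white) for visual inspection."""
    from PIL import Image

    dense = plot.to_dense(symmetric=True)
    img = Image.fromarray(np.where(dense, 0, 255).astype(np.uint8), mode="L")
    if scale > 1:
        img = img.resize((plot.n * scale, plot.n * scale), Image.NEAREST)
    img.save(os.fspath(path))


def file_digest(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | os.PathLike,
    command: str,
    parameters: dict,
    inputs: list[str | os.PathLike] = (),
    seed: int | None = None,
) -> None:
    """Emit a JSON run manifest: command, parameters, input digests, seed,
    tool version, timestamp."""
    from . import __version__

    manifest = {
        "command": command,
        "parameters": parameters,
        "inputs": {os.fspath(p): file_digest(p) for p in inputs if os.path.exists(p)},
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tsv(df, path: str | os.PathLike) -> None:
    """TSV with header, floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
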