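"""Run manifests: parameters, input digests and seeds for reproducibility."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(
    outdir: Path,
    subcommand: str,
    params: dict,
    inputs: dict[str, Optional[str]],
    seed: Optional[int],
) -> Path:
    """Write the single run manifest for an output directory."""
    from . import __version__

    manifest = {
        "tool": "scarscan",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": {k: v for k, v in params.items() if v is not None},
        "inputs": {
            name: {"path": str(p), "sha256_16": _digest(Path(p))}
            for name, p in inputs.items() if p is not None
        },
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
    }
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "scarscan.manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return path
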