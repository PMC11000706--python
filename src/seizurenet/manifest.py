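"""Run manifests: everything needed to re-execute a run byte-for-byte."""
from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def input_checksums(paths: list[str | Path], limit: int = 200) -> dict:
    """sha256 of input files (directories are walked, capped at ``limit``)."""
    out: dict[str, str] = {}
    for p in paths:
        p = Path(p)
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    out[str(f)] = _checksum(f)
                    if len(out) >= limit:
                        out["..."] = "truncated"
                        return out
        elif p.is_file():
            out[str(p)] = _checksum(p)
    return out


def build_manifest(command: str, seeds: dict, configs: dict | None = None,
                   inputs: list | None = None, extra: dict | None = None
                   ) -> dict:
    from . import __version__
    manifest = {
        "command": command,
        "argv": sys.argv,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seeds": seeds,
        "configs": configs or {},
        "input_checksums": input_checksums(inputs or []),
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(manifest: dict, out_dir: str | Path,
                   name: str = "manifest.json") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
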