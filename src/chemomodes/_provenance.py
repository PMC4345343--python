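"""Provenance stamping for TSV artifacts (config hash, input hashes, version)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def prepend_header(path: str | Path, meta: dict) -> None:
    """Rewrite a small text artifact with '# key: value' header lines on top."""
    path = Path(path)
    body = path.read_text()
    lines = "".join(f"# {k}: {v}\n" for k, v in meta.items())
    path.write_text(lines + body)
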