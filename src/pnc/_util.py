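"""Small shared helpers: seed derivation, provenance headers."""

from __future__ import annotations

import hashlib
import json
import zlib

from numpy.random import SeedSequence


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from one global seed.

    The split is a fixed function of (seed, stage name) so any stage can be
    rerun in isolation and reproduce the full-pipeline behaviour.
    """
    ss = SeedSequence([int(global_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def config_hash(params: dict) -> str:
    """12-hex-digit digest of a parameter mapping (canonical JSON)."""
    blob = json.dumps(params, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: int | None = None, params: dict | None = None) -> list[str]:
    from pnc import __version__

    lines = [f"# pnc {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if params is not None:
        lines.append(f"# config-hash={config_hash(params)}")
    return lines
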