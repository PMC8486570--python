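"""Pipeline configuration: defaults, flat key=value files, run logging."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .panel import DEFAULT_EXCLUSIONS


@dataclass
class PipelineConfig:
    """End-to-end settings; the defaults are the workflow's published ones
    (shrinkage threshold 0, lasso penalty 0.019, prioritization thresholds
    0.80/0.30, 100 bootstrap replicates, miR-122-5p/miR-21-5p excluded)."""

    panel_file: str | None = None
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    nsc_delta: float = 0.0
    lasso_lambda: float = 0.019
    rule_a_threshold: float = 0.80
    rule_b_threshold: float = 0.30
    n_boot: int = 100
    seed: int = 0
    log_transform: bool = True
    log_pseudocount: float = 0.01
    cluster_metric: str = "manhattan"
    cutoff_method: str = "roc"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key = value text file ('#' starts a comment)."""
        kwargs = {}
        known = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _coerce(key, raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def write_log(self, path: str | Path, message: str = "") -> None:
        from . import __version__

        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        lines = [
            f"[{stamp}] mirtoo {__version__}",
            f"config_hash={self.config_hash()} seed={self.seed}",
        ]
        if message:
            lines.append(message)
        with open(path, "a") as fh:
            fh.write("\n".join(lines) + "\n")


def _coerce(key: str, raw: str):
    if key in {"exclusions"}:
        return tuple(s.strip() for s in raw.split(",") if s.strip())
    if key in {"log_transform"}:
        return raw.lower() in {"1", "true", "yes"}
    if key in {"n_boot", "seed"}:
        return int(raw)
    if key in {"panel_file", "cluster_metric", "cutoff_method"}:
        return raw
    return float(raw)
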