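"""Pipeline orchestration helpers: run configuration, provenance headers,
seed management, structured logging.

All randomness flows from one top-level seed through named per-stage
substreams (``stage_seed``), so changing one stage's draws never perturbs
another stage's.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__version__ = "0.1.0"

__all__ = ["stage_seed", "write_table", "read_table", "RunContext"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31) from the run seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _provenance(seed, config_hash=""):
    return (f"# molclock v{__version__} seed={seed}"
            + (f" config={config_hash}" if config_hash else ""))


def write_table(df: pd.DataFrame, path, seed, config_hash="",
                force: bool = False, index: bool = False) -> None:
    """TSV with a provenance header line; refuses to overwrite without force."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (use force to overwrite)")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(seed, config_hash) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


@dataclass
class RunContext:
    """Output directory + seed + config for one pipeline invocation."""

    outdir: Path
    seed: int
    config: dict = field(default_factory=dict)
    force: bool = False
    log_lines: list = field(default_factory=list)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        blob = json.dumps(self.config, sort_keys=True, default=str)
        self.config_hash = hashlib.sha256(blob.encode()).hexdigest()[:12]

    def log(self, stage: str, msg: str, level: str = "INFO") -> None:
        line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{stage}\t{level}\t{msg}"
        self.log_lines.append(line)

    def flush_log(self) -> None:
        with open(self.outdir / "run.log", "a") as fh:
            for line in self.log_lines:
                fh.write(line + "\n")
        self.log_lines.clear()

    def write(self, df: pd.DataFrame, name: str, index: bool = False) -> Path:
        p = self.outdir / name
        write_table(df, p, self.seed, self.config_hash,
                    force=self.force, index=index)
        return p

    def write_text(self, text: str, name: str) -> Path:
        p = self.outdir / name
        if p.exists() and not self.force:
            raise FileExistsError(f"{p} exists (use force to overwrite)")
        with open(p, "w") as fh:
            fh.write(_provenance(self.seed, self.config_hash) + "\n" + text)
        return p

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)


def load_config(path) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
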