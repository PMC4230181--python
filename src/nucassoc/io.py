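"""Shared plumbing: BED probe annotations, run configuration, output headers.

All machine output is TSV with ``#`` header comments carrying the tool
version, a hash of the configuration and the seed, so a run can be
reproduced from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, FormatError
from .rsd import RSDConfig, default_config

__all__ = [
    "read_bed",
    "write_bed",
    "RunConfig",
    "write_table_with_header",
    "config_hash",
]

_BED_COLUMNS = ["chrom", "start", "end", "name"]


def read_bed(path) -> pd.DataFrame:
    """Read probe/segment annotations from BED (0-based, half-open).

    The name column holds the probe/segment id; strand and any further
    columns are ignored (FISH probes hybridise double-stranded).
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 4 BED columns, got {len(parts)}"
                )
            chrom, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: need 0 <= start < end, got [{start}, {end})"
                )
            rows.append({"chrom": chrom, "start": start, "end": end, "name": name})
    return pd.DataFrame(rows, columns=_BED_COLUMNS)


def write_bed(records: pd.DataFrame, path) -> None:
    records[_BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def config_hash(obj) -> str:
    """Short stable hash of a configuration object.

    The output location is excluded: where a report is written is not
    part of the analysis identity.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        obj = {k: v for k, v in obj.items() if k != "out_path"}
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table_with_header(df: pd.DataFrame, path, *, seed, config=None, index=False) -> None:
    """Write a TSV prefixed with '#' comments: version, config hash, seed."""
    with open(path, "w") as fh:
        fh.write(f"# nucassoc {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
        fh.write(f"# seed {seed}\n")
        df.to_csv(fh, sep="\t", index=index)


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of an end-to-end analysis run.

    Probe pairs are tested for association against a null expectation
    (``null_source``: the published reference constants or a fresh
    simulation on ``geometry``); optional expression inputs add
    per-segment mean expression and a co-expression label per pair.
    """

    nuclei_path: str | None = None
    probe_pairs: tuple[tuple[str, str, str], ...] = ()  # (probe_a, probe_b, relation)
    null_source: str = "reference"  # "reference" | "simulated"
    geometry: RSDConfig = field(default_factory=default_config)
    n_trials: int = 100_000
    expression_path: str | None = None
    segment_map_path: str | None = None
    expression_sample: str | None = None
    high_threshold: float = 0.7
    low_threshold: float = 0.3
    distance_threshold: "float | str" = "use-flags"
    seed: int = 0
    out_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "geometry" in raw:
            raw["geometry"] = RSDConfig(**raw["geometry"])
        if "probe_pairs" in raw:
            raw["probe_pairs"] = tuple(tuple(p) for p in raw["probe_pairs"])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**raw)
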