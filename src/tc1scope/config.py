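"""Pipeline configuration: YAML parsing, defaults, and invariant checks.

The config is a nested key/value file mirroring the generator and analysis
parameter names. Unknown keys are rejected; an empty file yields the
all-defaults configuration.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "ConfigError", "validate_config", "normalize_config"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "seed": 0,
    "stages": {"simulate": True, "famchar": True, "map": True, "signatures": True},
    "element": {
        "total_len": 1581,
        "ir_len": 199,
        "dr_len": 17,
        "orf_len": 1020,
        "pas_motif": "AATAAA",
    },
    "genome": {
        "genome_len": 500_000,
        "n_chrom": 2,
        "n_copies": 30,
        "sub_rate": 0.015,
        "n_intact": 5,
    },
    "reads": {
        "n_reads": 2000,
        "antisense_fraction": 0.943,
        "pingpong_fraction": 0.1,
        "u1_prob": 0.8,
        "a10_prob": 0.8,
        "length_preset": "27-28",  # or "24-25"
        "n_background": 500,
        "raw_read_len": 40,
        "append_adapter": True,
    },
    "famchar": {
        "primer_len": 37,
        "max_amplicon": 2000,
        "max_mismatch": 4,
        "threshold": 93.0,
        "ir_min_len": 30,
        "ir_min_identity": 90.0,
        "dr_min_len": 12,
    },
    "map": {
        "adapter": "ATCTCGTATGCCGTCTTCTGCTTG",
        "min_len": 20,
        "max_len": 32,
        "map_to_genome": True,
    },
    "signatures": {
        "pirna_db": None,  # optional FASTA/one-per-line reference piRNA set
    },
    "inputs": {
        # used when stage simulate is disabled
        "genome_fasta": None,
        "consensus_fasta": None,
        "reads_fastq": None,
        "transcripts_fasta": None,
    },
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict) and defaults[key]:
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"config key {here} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def _check_prob(cfg: dict, section: str, key: str, optional: bool = False) -> None:
    v = cfg[section][key]
    if v is None and optional:
        return
    if not isinstance(v, (int, float)) or not 0.0 <= float(v) <= 1.0:
        raise ConfigError(f"{section}.{key} must be in [0, 1], got {v!r}")


def normalize_config(user: dict | None) -> dict:
    """Apply defaults and check invariants on an already-parsed mapping."""
    cfg = _merge(DEFAULTS, user or {})
    _check_prob(cfg, "reads", "antisense_fraction")
    _check_prob(cfg, "reads", "pingpong_fraction")
    _check_prob(cfg, "reads", "u1_prob", optional=True)
    _check_prob(cfg, "reads", "a10_prob", optional=True)
    _check_prob(cfg, "genome", "sub_rate")
    if cfg["map"]["min_len"] > cfg["map"]["max_len"]:
        raise ConfigError(
            f"map.min_len ({cfg['map']['min_len']}) must be <= map.max_len ({cfg['map']['max_len']})"
        )
    if not 0 <= cfg["famchar"]["threshold"] <= 100:
        raise ConfigError(f"famchar.threshold must be in [0, 100], got {cfg['famchar']['threshold']}")
    if cfg["reads"]["length_preset"] not in ("27-28", "24-25"):
        raise ConfigError(f"reads.length_preset must be '27-28' or '24-25', got {cfg['reads']['length_preset']!r}")
    for section, key in [("genome", "n_copies"), ("genome", "n_intact"), ("reads", "n_reads"), ("reads", "n_background")]:
        v = cfg[section][key]
        if not isinstance(v, int) or v < 0:
            raise ConfigError(f"{section}.{key} must be a non-negative integer, got {v!r}")
    if cfg["genome"]["n_intact"] > cfg["genome"]["n_copies"]:
        raise ConfigError("genome.n_intact must be <= genome.n_copies")
    enabled = cfg["stages"]
    if not enabled["simulate"]:
        for stage, needed in [("famchar", ["genome_fasta", "consensus_fasta"]),
                              ("map", ["reads_fastq", "consensus_fasta"])]:
            if enabled[stage]:
                for inp in needed:
                    if cfg["inputs"][inp] is None:
                        raise ConfigError(f"stage {stage} enabled without simulate: inputs.{inp} is required")
    return cfg


def validate_config(path: str | Path) -> dict:
    """Parse a YAML config file, apply defaults, and check invariants."""
    text = Path(path).read_text()
    try:
        user = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ConfigError(f"could not parse config {path}: {e}") from e
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigError(f"config root must be a mapping, got {type(user).__name__}")
    return normalize_config(user)
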