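"""Campaign directory I/O and run provenance helpers.

A campaign on disk is a directory::

    campaign/
      manifest.yaml        # design, confounders, seed, truth model (if synthetic)
      sweeps/sweep_0001.csv ...   # '#'-prefixed metadata, then frequency_Hz,eps_real,eps_imag
      environment.csv      # per-sweep humidity / room temperature log
      validation/          # optional: pre_*.csv, post_*.csv, reference.json

CSV dialect: comma-separated, '.' decimal, UTF-8, metadata as leading
``# key: value`` lines.  Frequencies are serialized as integers when the
grid is exactly integral in Hz (the 25 MHz grid is), so round-trips are
drift-free.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import shutil
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .campaign import FrequencySweep, MeasurementCampaign
from .models import ColeColeModel, ColeColePole, TemperatureColeColeModel
from .synthetic import CampaignDesign, ConfounderConfig
from .uncertainty import ValidationPair

__all__ = [
    "config_hash",
    "read_campaign",
    "write_campaign",
    "read_sweep_csv",
    "write_sweep_csv",
    "atomic_directory",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


class atomic_directory:
    """Context manager: build a directory in a temp location, then move it
    into place on success; nothing partial is left behind on failure."""

    def __init__(self, target: Path):
        self.target = Path(target)

    def __enter__(self) -> Path:
        self.target.parent.mkdir(parents=True, exist_ok=True)
        self._tmp = Path(
            tempfile.mkdtemp(prefix=self.target.name + ".tmp-", dir=self.target.parent)
        )
        return self._tmp

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            if self.target.exists():
                shutil.rmtree(self.target)
            os.replace(self._tmp, self.target)
        else:
            shutil.rmtree(self._tmp, ignore_errors=True)


def _format_frequencies(f: np.ndarray) -> np.ndarray:
    if np.all(f == np.round(f)):
        return f.astype(np.int64)
    return f


_SWEEP_META_FIELDS = (
    "set_temperature",
    "actual_temperature",
    "sample_id",
    "site_id",
    "contact_pressure_kPa",
    "weight_before_g",
    "weight_after_g",
)


def write_sweep_csv(sweep: FrequencySweep, path, extra_meta: Optional[dict] = None) -> None:
    meta = {k: getattr(sweep, k) for k in _SWEEP_META_FIELDS if getattr(sweep, k) is not None}
    if extra_meta:
        meta.update(extra_meta)
    df = pd.DataFrame(
        {
            "frequency_Hz": _format_frequencies(sweep.frequencies),
            "eps_real": sweep.eps_real,
            "eps_imag": sweep.eps_imag,
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_sweep_csv(path) -> FrequencySweep:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" not in body:
                raise ValueError(f"{path}:{lineno}: malformed metadata line {line!r}")
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # surface the offending file
        raise ValueError(f"{path}: cannot parse sweep CSV ({exc})") from exc
    for col in ("frequency_Hz", "eps_real", "eps_imag"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "actual_temperature" not in meta:
        raise ValueError(f"{path}: metadata must record actual_temperature")

    def opt(key, cast):
        return cast(meta[key]) if key in meta else None

    return FrequencySweep(
        frequencies=df["frequency_Hz"].to_numpy(dtype=float),
        eps_real=df["eps_real"].to_numpy(dtype=float),
        eps_imag=df["eps_imag"].to_numpy(dtype=float),
        actual_temperature=float(meta["actual_temperature"]),
        set_temperature=opt("set_temperature", float),
        sample_id=opt("sample_id", int),
        site_id=opt("site_id", int),
        contact_pressure_kPa=opt("contact_pressure_kPa", float),
        weight_before_g=opt("weight_before_g", float),
        weight_after_g=opt("weight_after_g", float),
    )


def _confounders_to_dict(cfg: ConfounderConfig) -> dict:
    d = dataclasses.asdict(cfg)
    tail = cfg.delta_tail
    d["delta_tail"] = (
        None if tail is None else {"delta_eps": tail.delta_eps, "tau_s": tail.tau, "alpha": tail.alpha}
    )
    return d


def _confounders_from_dict(d: dict) -> ConfounderConfig:
    d = dict(d)
    tail = d.get("delta_tail")
    if tail is not None:
        d["delta_tail"] = ColeColePole(tail["delta_eps"], tail["tau_s"], tail["alpha"])
    return ConfounderConfig(**d)


def write_campaign(
    campaign: MeasurementCampaign,
    path,
    design: Optional[CampaignDesign] = None,
    confounders: Optional[ConfounderConfig] = None,
) -> str:
    """Write a campaign directory atomically; returns the manifest hash."""
    manifest: dict = {
        "n_sweeps": len(campaign),
        "design": dataclasses.asdict(design) if design else None,
        "confounders": _confounders_to_dict(confounders) if confounders else None,
        "truth": campaign.truth.to_dict() if campaign.truth is not None else None,
    }
    manifest["config_hash"] = config_hash(
        {k: manifest[k] for k in ("design", "confounders", "truth")}
    )
    with atomic_directory(Path(path)) as tmp:
        sweep_dir = tmp / "sweeps"
        sweep_dir.mkdir()
        for i, sweep in enumerate(campaign.sweeps, start=1):
            write_sweep_csv(sweep, sweep_dir / f"sweep_{i:04d}.csv")
        if campaign.environment_log is not None:
            campaign.environment_log.to_csv(tmp / "environment.csv", index=False)
        if campaign.validation is not None:
            vdir = tmp / "validation"
            vdir.mkdir()
            for i, sw in enumerate(campaign.validation.pre_sweeps, start=1):
                write_sweep_csv(sw, vdir / f"pre_{i:02d}.csv")
            for i, sw in enumerate(campaign.validation.post_sweeps, start=1):
                write_sweep_csv(sw, vdir / f"post_{i:02d}.csv")
            campaign.validation.reference.to_json(vdir / "reference.json")
        with open(tmp / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False, allow_unicode=True)
    return manifest["config_hash"]


def read_campaign(path) -> MeasurementCampaign:
    """Load a campaign directory written by :func:`write_campaign`."""
    path = Path(path)
    if not path.is_dir():
        raise ValueError(f"{path} is not a campaign directory")
    sweep_dir = path / "sweeps"
    if not sweep_dir.is_dir():
        raise ValueError(f"{path}: missing sweeps/ subdirectory")
    sweeps = [read_sweep_csv(p) for p in sorted(sweep_dir.glob("*.csv"))]
    if not sweeps:
        raise ValueError(f"{path}: no sweep files found")

    truth = None
    manifest_path = path / "manifest.yaml"
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = yaml.safe_load(fh) or {}
        if manifest.get("truth"):
            truth = TemperatureColeColeModel.from_dict(manifest["truth"])

    env = None
    env_path = path / "environment.csv"
    if env_path.exists():
        env = pd.read_csv(env_path)

    validation = None
    vdir = path / "validation"
    if vdir.is_dir():
        pre = [read_sweep_csv(p) for p in sorted(vdir.glob("pre_*.csv"))]
        post = [read_sweep_csv(p) for p in sorted(vdir.glob("post_*.csv"))]
        ref_path = vdir / "reference.json"
        if pre and post and ref_path.exists():
            validation = ValidationPair(pre, post, ColeColeModel.from_json(ref_path))

    return MeasurementCampaign(
        sweeps=sweeps, validation=validation, environment_log=env, truth=truth
    )


def read_manifest(path) -> dict:
    with open(Path(path) / "manifest.yaml", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def design_from_manifest(manifest: dict) -> Optional[CampaignDesign]:
    d = manifest.get("design")
    if d is None:
        return None
    d = dict(d)
    d["set_temperatures"] = tuple(d["set_temperatures"])
    return CampaignDesign(**d)


def confounders_from_manifest(manifest: dict) -> Optional[ConfounderConfig]:
    c = manifest.get("confounders")
    return None if c is None else _confounders_from_dict(c)
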