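"""Configuration loading and table export.

Config files are YAML (or JSON, a YAML subset) with one namespace per
parameter group (``cell:``, ``ca:``, ``passive:``, ``geometry:``,
``circulation:``, ``sim:``, plus optional ``tvem:`` and ``isovelocity:``).
Omitted keys fall back to the published defaults; unknown keys are
rejected as typo protection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .params import IsovelocityConfig, ModelParams, TVEMParams

__all__ = ["RunConfig", "load_config", "dump_config", "export_tables"]


@dataclass(frozen=True)
class RunConfig:
    """Full parameter bundle for a run, including protocol settings."""

    model: ModelParams
    tvem: TVEMParams
    isovelocity: IsovelocityConfig

    def to_dict(self) -> dict:
        d = self.model.to_dict()
        d["tvem"] = {f.name: getattr(self.tvem, f.name) for f in fields(TVEMParams)}
        d["isovelocity"] = {
            f.name: (list(v) if isinstance(v := getattr(self.isovelocity, f.name), tuple) else v)
            for f in fields(IsovelocityConfig)
        }
        return d


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON config; a missing path yields the full defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    tvem_kw = data.pop("tvem", {})
    iso_kw = data.pop("isovelocity", {})
    for name, cls, kw in (("tvem", TVEMParams, tvem_kw),
                          ("isovelocity", IsovelocityConfig, iso_kw)):
        bad = set(kw) - {f.name for f in fields(cls)}
        if bad:
            raise KeyError(f"unknown key(s) in '{name}': {sorted(bad)}")
    if "velocities" in iso_kw:
        iso_kw["velocities"] = tuple(iso_kw["velocities"])
    return RunConfig(
        model=ModelParams.from_dict(data),
        tvem=TVEMParams(**tvem_kw),
        isovelocity=IsovelocityConfig(**iso_kw),
    )


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config that round-trips through :func:`load_config`."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def export_tables(series, out_dir: str | Path, prefix: str = "elastance"
                  ) -> tuple[Path, Path]:
    """Write the isochronous-elastance and F_ext–L slope tables as CSV.

    Columns mirror the study layout (t, E_inst, E_load, V_0, R2) and
    (t, k_a, R2); floats are written at 4 decimals.  A partial series
    produces explicit NA cells and a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t7 = series.table7()
    t8 = series.table8()
    if t7.isna().any().any() or t8.isna().any().any():
        warnings.warn("elastance series is incomplete; writing NA cells", stacklevel=2)
    p7 = out_dir / f"{prefix}_pv.csv"
    p8 = out_dir / f"{prefix}_tension_length.csv"
    t7.to_csv(p7, index=False, float_format="%.4f")
    t8.to_csv(p8, index=False, float_format="%.4f")
    return p7, p8
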