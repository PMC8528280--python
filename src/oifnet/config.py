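"""Run configuration: a fully serializable description of one analysis run.

A results bundle is reproducible from its archived config alone; every output
file in a bundle is stamped with the config hash so mixed bundles are
detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # inputs
    census: str = ""                 # census CSV path ("" -> synthetic)
    species_meta: str | None = None
    # estimator settings
    estimator: str = "gaussian"
    u_max: int = 10
    bins: int = 8
    bandwidth: float = 0.5
    # partitions and windows
    tr_edges: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0)
    time_window: int = 24
    time_step: int = 2
    temp_window_l: int = 10          # upper limit of the first temperature window
    temp_step: int = 1
    temp_width: float = 5.0
    # thresholding
    threshold_mode: str = "fixed"    # fixed | pareto20 | alpha_opt | none
    threshold_value: float | None = None
    # salience / keystone
    salience_directed: bool = True
    keystone_endpoint: str = "both"
    top_k: int = 5
    # report
    report_convention: str = "annual_mean"   # annual_mean | single_point
    # reproducibility
    seed: int = 0
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides
    outdir: str = "oifnet_results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tr_edges"] = list(self.tr_edges)
        return d

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "tr_edges" in data:
        data["tr_edges"] = tuple(data["tr_edges"])
    return RunConfig(**data)
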