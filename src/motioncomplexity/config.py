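"""Analysis configuration, loadable from a YAML key/value file."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .trajectory_core import DEFAULT_N, DEFAULT_T, Workspace

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of the complexity pipeline with their defaults."""

    T: int = DEFAULT_T                  # samples per trajectory after resampling
    n_expected: int = DEFAULT_N         # repetitions per pattern
    workspace_width: float = 10.0       # cm
    workspace_height: float = 10.0      # cm
    cell_size: float = 1.0              # cm, symbolisation grid
    gp_concat: str = "block"            # "block" or "continuous"
    pmp_n_basis: int = 20               # bases per dimension
    pmp_h: float | None = None          # basis width; default 1/(n-1)
    kappa0: float = 0.1                 # NIW prior strength
    nu0: float = 10.0                   # NIW prior degrees of freedom
    sigma_tau: float = 1e-10            # trajectory observation noise
    min_transitions: int = 10_000       # corpus length for symbol measures
    l_max: int = 8                      # max block length for EMC
    seed: int = 0

    @property
    def workspace(self) -> Workspace:
        return Workspace(self.workspace_width, self.workspace_height, self.cell_size)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from YAML; None gives the defaults."""
    if path is None:
        return AnalysisConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)
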