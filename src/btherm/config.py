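"""Run-wide configuration.

All numeric knobs that the analysis stages consult live here so that a run
can be reproduced from a single key=value file.  Defaults mirror the
conventions of the CCP4-style tools the pipeline emulates (unweighted
averages, Calpha-only global superposition).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict


@dataclass
class AnalysisConfig:
    #: how alternate locations are collapsed: "highest_occupancy" or "first"
    altloc_policy: str = "highest_occupancy"
    #: atom class used for the global rigid superposition ("calpha" or "backbone")
    fit_selection: str = "calpha"
    #: waters further than this (Angstrom) from any reference water are unmatched
    water_cutoff: float = 1.0
    #: fraction of structures a reference water must be matched in to count
    #: as conserved (1.0 = matched in every structure)
    conserved_fraction: float = 1.0
    #: per-residue thermal fits require the residue in at least this fraction
    #: of the structures in the series
    min_coverage_fraction: float = 2.0 / 3.0
    #: exponential fit: stop when the relative loss change drops below this
    exp_tol: float = 1e-10
    #: exponential fit: iteration cap
    exp_max_iter: int = 200
    #: whether zero-occupancy atoms enter B-factor aggregation
    include_zero_occupancy: bool = False
    #: whether B-factor averages are occupancy-weighted (default: unweighted)
    occupancy_weighting: bool = False
    #: OXT counted with the backbone (flip to classify it as side chain)
    oxt_is_backbone: bool = True
    #: structure_id -> Kelvin; wins over the REMARK 200 header value
    temperature_overrides: Dict[str, float] = field(default_factory=dict)
    #: seed echoed into run logs and used by stages that need randomness
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a plain ``key = value`` file; unknown keys are rejected.

        Temperature overrides use keys of the form ``temperature.<ID> = 225``.
        """
        cfg = cls()
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value, got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key.startswith("temperature."):
                cfg.temperature_overrides[key.split(".", 1)[1]] = float(val)
                continue
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = fields[key].type
            if typ == "bool":
                setattr(cfg, key, val.lower() in ("1", "true", "yes", "on"))
            elif typ == "int":
                setattr(cfg, key, int(val))
            elif typ == "float":
                setattr(cfg, key, float(val))
            else:
                setattr(cfg, key, val)
        return cfg

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            if f.name == "temperature_overrides":
                for sid, t in self.temperature_overrides.items():
                    lines.append(f"temperature.{sid} = {t}")
            else:
                lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")


DEFAULT_CONFIG = AnalysisConfig()
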