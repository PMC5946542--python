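"""Pipeline configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .parsimony import ACCTRAN, DELTRAN


@dataclass
class PipelineConfig:
    """Tunable thresholds and paths shared by all commands.

    nc_threshold_bp — unannotated gaps at least this long become NC tokens
    (bp); cr_asymmetry_ratio — CR length max/min ratio above which a CR
    pair counts as asymmetric; anchor — gene at which circles are
    linearized; resolution_mode — DELTRAN (delay transformations; default)
    or ACCTRAN.
    """

    nc_threshold_bp: int = 50
    cr_asymmetry_ratio: float = 1.2
    anchor: str = "F"
    resolution_mode: str = DELTRAN
    seed: int = 0
    output_dir: Path = field(default_factory=lambda: Path("."))

    def __post_init__(self) -> None:
        if self.nc_threshold_bp <= 0 or self.cr_asymmetry_ratio <= 0:
            raise ValueError("thresholds must be positive")
        if self.resolution_mode not in (DELTRAN, ACCTRAN):
            raise ValueError(
                f"resolution_mode must be {DELTRAN} or {ACCTRAN}"
            )
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(d["output_dir"])
        return d
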