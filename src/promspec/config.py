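"""Pipeline configuration: every tunable in one validated mapping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .alignment import ScoringScheme
from .pb import PBParameters


@dataclass
class PipelineConfig:
    """All pipeline tunables with their documented defaults.

    Unknown keys in a config file are rejected on load.
    """

    # alignment
    gap_open: float = 20.0
    gap_extend: float = 0.5
    end_gaps_free: bool = True
    align_mode: str = "global"
    null_replicates: int = 1
    # clustering
    adjacency_norm: str = "max"
    k_max: int = 15
    kmeans_tol: float = 1e-6
    kmeans_restarts: int = 50
    seed: int = 0
    # lattice model
    pb_k: float = 0.025
    pb_rho: float = 2.0
    pb_alpha: float = 0.35
    pb_D_W: float = 0.05
    pb_D_S: float = 0.075
    pb_a_W: float = 4.2
    pb_a_S: float = 6.9
    # region detection
    P_thr: float = 4.0
    eps: float = 0.01
    delta: float = 1e-4
    tol: float = 0.3
    min_len: int = 7
    extension_def: str = "threshold"  # or "rms"
    # composition / TATA
    tata_window: tuple[int, int] = field(default=(-40, -19))
    dinucleotide_window: int = 1
    top_k: int = 15
    # repeats
    overlap_rule: str = "contained"
    # ambiguity handling
    allow_n: str = "drop"  # or "mask"

    def __post_init__(self) -> None:
        if self.align_mode not in ("global", "local"):
            raise ValueError(f"bad align_mode {self.align_mode!r}")
        if self.adjacency_norm not in ("max", "minself", "none"):
            raise ValueError(f"bad adjacency_norm {self.adjacency_norm!r}")
        if self.overlap_rule not in ("contained", "any_overlap"):
            raise ValueError(f"bad overlap_rule {self.overlap_rule!r}")
        if self.allow_n not in ("drop", "mask"):
            raise ValueError(f"bad allow_n {self.allow_n!r}")
        self.tata_window = tuple(self.tata_window)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable digest over all effective parameters."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def scoring_scheme(self) -> ScoringScheme:
        return ScoringScheme(
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            end_gaps_free=self.end_gaps_free,
            mode=self.align_mode,
        )

    def pb_parameters(self) -> PBParameters:
        return PBParameters(
            k=self.pb_k,
            rho=self.pb_rho,
            alpha=self.pb_alpha,
            D_W=self.pb_D_W,
            D_S=self.pb_D_S,
            a_W=self.pb_a_W,
            a_S=self.pb_a_S,
        )
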