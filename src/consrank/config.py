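"""Pipeline configuration.

All tunable constants of the scoring pipeline live in one frozen-ish
dataclass so that a run is fully described by (inputs, config).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """Constants controlling contact definition, clustering and selection.

    Attributes
    ----------
    contact_cutoff : float
        Two residues on different chains are in contact if any pair of
        heavy atoms is closer than this distance (Å).
    clash_cutoff : float
        Inter-chain heavy-atom pairs closer than this distance (Å) count
        as steric clashes.
    clash_max : int
        Candidates with more than this many clashes are excluded from the
        final selection.
    maxscore_threshold : float
        Consensus-sharpness threshold on the Maxscore (normalized score of
        the top-ranked model).  At or above it the consensus is considered
        strong and all submissions come from the consensus ranking; below
        it the selection is diversified across clusters.
    top_consrank_pool : int
        Number of top consensus-ranked models entering the candidate pool.
    top_clusters : int
        Number of most-populated clusters contributing candidates.
    per_cluster : int
        Candidates taken from each of the top clusters.
    n_submit : int
        Size of the final ranked selection.
    seq_identity_min, coverage_min : float
        Per-chain sequence identity / target coverage required for a model
        to be considered a model of the target.
    sasa_probe_radius : float
        Solvent probe radius (Å) for accessible-surface computation.
    sasa_n_points : int
        Quadrature points per atom for the Shrake-Rupley surface.
    interface_area_convention : str
        "mean" reports the average buried surface of the two partners,
        "sum" reports the total buried surface.
    """

    contact_cutoff: float = 5.0
    clash_cutoff: float = 3.0
    clash_max: int = 25
    maxscore_threshold: float = 0.1
    top_consrank_pool: int = 30
    top_clusters: int = 15
    per_cluster: int = 2
    n_submit: int = 10
    seq_identity_min: float = 0.90
    coverage_min: float = 0.70
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    interface_area_convention: str = "mean"

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.clash_cutoff <= 0:
            raise ValueError("distance cutoffs must be positive")
        if self.sasa_probe_radius < 0 or self.sasa_n_points < 1:
            raise ValueError("invalid SASA parameters")
        if self.n_submit > self.top_consrank_pool + self.top_clusters * self.per_cluster:
            raise ValueError(
                "n_submit exceeds the maximum candidate pool "
                f"({self.top_consrank_pool} + {self.top_clusters}x{self.per_cluster})"
            )
        if self.interface_area_convention not in ("mean", "sum"):
            raise ValueError("interface_area_convention must be 'mean' or 'sum'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML or JSON file (keys = field names)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
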