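"""Pipeline configuration: every numeric threshold in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunables of the curation pipeline.

    Defaults follow the published workflow: two-round translated-search
    expect cutoffs of 1e-4 then 1e-3; the strict >80% bacterial-identity
    contamination rule; TIR lengths 24-462 bp (soft; discovery floor 10);
    TSD k of 7-10 with 8/9 preferred; domain size filter >115 aa; 70%
    identity clustering; 0.4 gap-threshold trimming; <110 aa final filter;
    1000 bootstrap replicates.  The 0.25 family-linkage p-distance is a
    package decision (no published number exists).
    """

    evalue_round1: float = 1e-4
    evalue_round2: float = 1e-3
    contamination_identity: float = 0.80
    tir_len_range: tuple[int, int] = (24, 462)
    tir_min_discovery: int = 10
    tsd_k_range: tuple[int, ...] = (7, 8, 9, 10)
    domain_min_aa: int = 115
    final_min_aa: int = 110
    cluster_identity: float = 0.70
    trim_gap_threshold: float = 0.4
    bootstrap_reps: int = 1000
    family_linkage: float = 0.25
    flank_bp: int = 2000
    min_orf_aa: int = 80
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.evalue_round1 <= self.evalue_round2:
            raise ValueError("expect cutoffs must satisfy 0 < round1 <= round2")
        if not 0.0 < self.contamination_identity < 1.0:
            raise ValueError("contamination_identity must be in (0, 1)")
        if not 0.0 < self.cluster_identity <= 1.0:
            raise ValueError("cluster_identity must be in (0, 1]")
        if not 0.0 <= self.trim_gap_threshold <= 1.0:
            raise ValueError("trim_gap_threshold must be in [0, 1]")
        if not 0.0 < self.family_linkage < 1.0:
            raise ValueError("family_linkage must be in (0, 1)")
        if self.tir_len_range[0] < 2 or \
                self.tir_len_range[0] > self.tir_len_range[1]:
            raise ValueError("tir_len_range must be an increasing pair")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tir_len_range"] = list(self.tir_len_range)
        d["tsd_k_range"] = list(self.tsd_k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "tir_len_range" in d:
            d["tir_len_range"] = tuple(d["tir_len_range"])
        if "tsd_k_range" in d:
            d["tsd_k_range"] = tuple(d["tsd_k_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=1)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        doc = (json.loads(path.read_text()) if path.suffix == ".json"
               else yaml.safe_load(path.read_text()))
        return cls.from_dict(doc)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
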