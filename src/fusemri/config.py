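"""Experiment configuration for the end-to-end driver."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ParameterError
from .ranking import RankingConfig

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run.

    ``task`` selects the classification question: ``diagnosis`` (patients
    vs controls) or ``outcome`` (positive vs negative 6-month outcome,
    derived from the HDRS reduction rule; subjects without follow-up are
    dropped).
    """

    task: str = "diagnosis"
    features_dir: str = "features"
    clinical_path: str = "clinical.csv"
    output_dir: str = "reports"
    ranking: RankingConfig = field(default_factory=RankingConfig)
    ensemble_sizes: tuple = (3, 5)
    n_perm: int = 1000
    n_boot: int = 1000
    seed: int = 0

    def validate(self, check_paths: bool = False) -> None:
        if self.task not in ("diagnosis", "outcome"):
            raise ParameterError(f"unknown task {self.task!r}")
        self.ranking.validate()
        for n_set in self.ensemble_sizes:
            if n_set % 2 == 0 or n_set < 3:
                raise ParameterError("ensemble sizes must be odd and >= 3")
        if check_paths:
            for p in (self.features_dir, self.clinical_path):
                if not Path(p).exists():
                    raise ParameterError(f"path does not exist: {p}")

    def echo(self) -> dict:
        d = asdict(self)
        d["ensemble_sizes"] = list(self.ensemble_sizes)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        rk = raw.pop("ranking", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__},
                  ranking=RankingConfig(**rk))
        if "ensemble_sizes" in raw:
            cfg.ensemble_sizes = tuple(raw["ensemble_sizes"])
        return cfg
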