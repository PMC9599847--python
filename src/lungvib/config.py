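"""Run-level configuration shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields


@dataclass
class PipelineConfig:
    """Every tunable of the analysis chain, with the package defaults.

    Validated as a whole before any stage runs and persisted verbatim into
    output artifacts so runs are reproducible from their own metadata.
    """

    # buffering
    buffer_s: float = 60.0
    step_s: float = 30.0
    # landmark detection
    hp_cutoff: float = 15.0  # Hz, heart-sound high-pass
    lp_cutoff: float = 1.0  # Hz, respiration low-pass
    min_separation_ms: float = 200.0  # envelope-peak refractory period
    smooth_ms: float = 20.0  # envelope moving-average window
    # spectrogram
    window_s: float = 2.0
    overlap_frac: float = 0.75
    # feature grid
    bands: tuple = (
        (0.5, 1.0),
        (1.0, 2.0),
        (2.0, 4.0),
        (4.0, 8.0),
        (8.0, 16.0),
        (16.0, 32.0),
        (32.0, 64.0),
    )
    buffer_aggregation: str = "mean"  # or "median"
    # classifier
    n_rounds: int = 50
    eps_floor: float = 1e-10
    max_na_frac: float = 0.05
    # evaluation
    k_folds: int = 10
    n_boot: int = 1000
    external_prevalence: float = 0.32
    na_policy: str = "exclude"  # or "count_as_error"
    seed: int = 0

    def validate(self) -> None:
        if self.buffer_s <= 0 or self.step_s <= 0:
            raise ValueError("buffer_s and step_s must be positive")
        if not (0 <= self.max_na_frac < 1):
            raise ValueError("max_na_frac must be in [0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0 < self.external_prevalence < 1):
            raise ValueError("external_prevalence must be in (0, 1)")
        if self.na_policy not in ("exclude", "count_as_error"):
            raise ValueError(f"unknown na_policy {self.na_policy!r}")
        if self.buffer_aggregation not in ("mean", "median"):
            raise ValueError("buffer_aggregation must be 'mean' or 'median'")
        if self.n_rounds < 1 or self.n_boot < 1:
            raise ValueError("n_rounds and n_boot must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(tuple(b) for b in d["bands"])
        cfg = cls(**d)
        cfg.validate()
        return cfg
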