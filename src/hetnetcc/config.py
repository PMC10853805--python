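"""Pipeline configuration: hyperparameters, validation, flat YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable knobs of the co-clustering pipeline.

    Parameters
    ----------
    k
        Number of co-clusters (columns of G1/G2). Must be >= 2.
    alpha, beta, gamma
        Non-negative coefficients of the joint objective: ``alpha`` weighs the
        expression factorization, ``beta`` the orthogonality penalty on the
        cluster-distribution matrices, ``gamma`` the squared-norm regularizer
        that keeps the view weights away from a one-hot solution.
    t
        Number of top-scoring novel cross-layer pairs retained per refined
        association matrix. ``None`` means "as many as there are known
        interactions" (density doubling), resolved at fusion time.
    T1, T2
        Column z-score thresholds for gene / miRNA module membership.
    d_ini
        Attribute dimensionality after PCA; clipped to the data rank.
    hidden_dim, latent_dim, epochs, learning_rate
        VGAE encoder hyperparameters.
    max_iter, tol
        Alternating-optimization budget and relative-change stopping rule.
    seed
        Base seed for every random draw in the pipeline.
    log2_expression
        Apply log2(x+1) to expression matrices before use.
    binarize_associations
        Refined association matrices carry 0/1 entries (default) rather than
        raw reconstruction scores.
    """

    k: int = 3
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    t: int | None = None
    T1: float = 1.0
    T2: float = 1.0
    d_ini: int = 64
    hidden_dim: int = 32
    latent_dim: int = 16
    epochs: int = 200
    learning_rate: float = 0.01
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    log2_expression: bool = False
    binarize_associations: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        for name in ("alpha", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.t is not None and self.t < 0:
            raise ValueError("t must be a non-negative integer or None")
        if self.d_ini < 1:
            raise ValueError("d_ini must be a positive integer")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        for name in ("hidden_dim", "latent_dim", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    # -- flat key-value serialization ------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a flat key-value mapping")
        return cls.from_dict(data)
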