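"""Run configuration: hyperparameters, validation, seed derivation."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


def derive_seed(master: int, *tags: object) -> int:
    """Derive a stage seed (< 2**31) from a master seed and string tags.

    The rule is a documented, platform-stable hash: the master seed plus the
    CRC32 of each tag feed a ``numpy.random.SeedSequence``.  Every source of
    randomness in a run draws its seed through this function, so one master
    seed reproduces the whole pipeline.
    """
    entropy = [int(master)] + [zlib.crc32(str(t).encode()) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """All pipeline hyperparameters with their defaults.

    Encoder: two GCN layers of 96 and 48 units; classifier: three hidden
    layers of 128/64/32 units with dropout 0.5; both stages train 50 epochs
    with Adam at learning rate 0.005.  Evaluation uses an 80/20 split
    repeated 5 times with 5-fold cross-validation inside the training part.
    """

    hidden1: int = 96
    embed_dim: int = 48          # latent dimension P
    lr: float = 0.005
    epochs: int = 50
    encoder_dropout: float = 0.0
    propagation_mode: str = "raw"      # "raw" | "signed_sym_norm"
    kl_scale: str | float = "per_node"  # KL divided by N, or an explicit factor
    pos_weight: str | float = "balanced"

    classifier_layers: tuple[int, ...] = (128, 64, 32)
    classifier_dropout: float = 0.5
    classifier_epochs: int = 50
    classifier_lr: float = 0.005

    normalize_ct: bool = True
    symmetrize: bool = True
    threshold: float = 0.5

    test_fraction: float = 0.2
    n_repeats: int = 5
    n_folds: int = 5
    species: str | None = None   # species filter tag; None skips criterion 1

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr:
            raise ValueError("lr must be positive")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        for name in ("encoder_dropout", "classifier_dropout"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.propagation_mode not in ("raw", "signed_sym_norm"):
            raise ValueError(f"unknown propagation_mode '{self.propagation_mode}'")
        if self.epochs < 0 or self.classifier_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        self.classifier_layers = tuple(self.classifier_layers)

    def stage_seed(self, *tags: object) -> int:
        return derive_seed(self.seed, *tags)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classifier_layers"] = list(self.classifier_layers)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
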