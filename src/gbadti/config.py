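"""Run configuration: model dimensions, loss weights and training knobs.

Full-scale defaults: Morgan fingerprints of
1024 bits, 1280-dim protein features, towers of sizes [2048, 512], loss
weight lambda = 1/3, rank-transform root t = 3, Adam at 1e-5 for up to 2000
steps, 1:1 negative sampling and a 7:1:2 random split.  Synthetic desk-scale
runs override the dimensions (see :func:`RunConfig.small`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from gbadti.errors import FormatError, ValidationError


@dataclass(frozen=True)
class RunConfig:
    d_m: int = 1024            # drug input (fingerprint) dimension
    d_t: int = 1280            # protein input feature dimension
    d_h: int = 2048            # hidden layer width of both towers
    d_s: int = 512             # shared embedding dimension
    lambda_weight: float = 1 / 3   # weight of the interaction loss term
    t_root: float = 3.0        # t-th root of the rank-reciprocal transform
    learning_rate: float = 1e-5
    max_iterations: int = 2000
    batch_size: int = 256
    neg_ratio: int = 1         # negatives sampled per training positive
    seed: int = 0
    train_fraction: float = 0.7
    val_fraction: float = 0.1
    test_fraction: float = 0.2
    decision_threshold: float | None = None  # None -> tune on validation

    def __post_init__(self):
        for name in ("d_m", "d_t", "d_h", "d_s"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        if self.lambda_weight < 0:
            raise ValidationError("lambda_weight must be >= 0")
        if self.t_root < 1:
            raise ValidationError("t_root must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.max_iterations < 1 or self.batch_size < 1 or self.neg_ratio < 0:
            raise ValidationError("max_iterations/batch_size must be >= 1, neg_ratio >= 0")
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"split fractions must sum to 1, got {total}")

    @classmethod
    def small(cls, **overrides) -> "RunConfig":
        """Reduced-dimension config for synthetic desk-scale experiments."""
        base = dict(
            d_m=64, d_t=32, d_h=32, d_s=16,
            learning_rate=1e-3, max_iterations=600,
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **overrides)

    # -- flat key=value round trip -------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {'' if v is None else v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat ``key = value`` document; keyword overrides win."""
        kwargs = {}
        field_types = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(
                    f"expected 'key = value' at {path}:{lineno}: {line!r}"
                )
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in field_types:
                raise ValidationError(f"unknown config key {key!r} at {path}:{lineno}")
            kwargs[key] = _coerce(key, value)
        kwargs.update(overrides)
        return cls(**kwargs)


def _coerce(key: str, value: str):
    if value == "":
        return None
    if key in ("d_m", "d_t", "d_h", "d_s", "max_iterations", "batch_size",
               "neg_ratio", "seed"):
        return int(value)
    return float(value)
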