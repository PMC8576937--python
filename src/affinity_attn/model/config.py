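"""Hyperparameter configuration for the affinity network."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class ModelConfig:
    """All tunable dimensions and training settings.

    The reference geometry (``column_dense_out=5``, ``h=53``) makes the
    convolutional input 265 long, so the five branch outputs flatten and
    concatenate to exactly 513 values before the Vina terms are merged in.
    ``use_vina`` / ``use_attention`` wire the ablation variants: descriptors
    only (D), D+A, D+V and the full D+V+A model.
    """

    u: int
    h: int = 53
    column_dense_out: int = 5
    window_sizes: tuple[int, ...] = (2, 4, 6, 8, 10)
    filters_per_depth: tuple[int, ...] = (3, 6, 6, 9)
    pool_size: int = 2
    encoded_dim: int = 128
    attention_dim: int = 64
    context_dim: int = 64
    ffn_sizes: tuple[int, ...] = (512, 256, 128)
    lr: float = 0.005
    batch_size: int = 256
    l2_lambda: float = 1e-4
    seed: int = 0
    epochs: int = 120
    patience: int = 20
    use_vina: bool = True
    use_attention: bool = True

    def __post_init__(self) -> None:
        if len(self.window_sizes) != 5:
            raise ValueError("five convolution window sizes are required")
        if len(self.filters_per_depth) != 4:
            raise ValueError("four convolution depths are required")
        if self.pool_size != 2:
            raise ValueError("only pool size 2 (stride 2) is supported")
        for name in ("u", "h", "column_dense_out", "encoded_dim", "attention_dim", "context_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for window in self.window_sizes:
            if self.branch_output_length(window) < 1:
                raise ValueError(
                    f"conv input length {self.conv_input_length} too short for window {window}"
                )

    @property
    def conv_input_length(self) -> int:
        return self.column_dense_out * self.h

    def branch_output_length(self, window: int) -> int:
        length = self.conv_input_length
        for _ in self.filters_per_depth:
            length = (length - window + 1) // self.pool_size
        return length

    @property
    def flatten_length(self) -> int:
        """Size of the concatenated conv output before Vina fusion."""
        last = self.filters_per_depth[-1]
        return sum(last * self.branch_output_length(w) for w in self.window_sizes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        data = dict(data)
        for key in ("window_sizes", "filters_per_depth", "ffn_sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
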