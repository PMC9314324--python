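"""The segmentation model: chained residual blocks, a gated recurrent
layer, and a per-position fully connected projection to 4 class channels.

Input (B, 1, L) -> output logits (B, 4, L) for any L >= kernel_size; the
length axis is preserved end to end (no pooling or striding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._layers import (
    DTYPE,
    GRU,
    Param,
    PositionwiseLinear,
    ResBlock1d,
    softmax,
)

__all__ = ["ModelConfig", "QrsSegmenter", "build_model", "infer",
           "save_model", "load_model"]

DEFAULT_CHANNELS = [16, 32, 64, 128, 128]


@dataclass
class ModelConfig:
    n_res_blocks: int = 5
    channels_per_block: list[int] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    kernel_size: int = 7
    gru_hidden: int = 128
    gru_bidirectional: bool = False
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res_blocks < 1:
            raise ValueError("n_res_blocks must be >= 1")
        if len(self.channels_per_block) != self.n_res_blocks:
            raise ValueError(
                f"channels_per_block has {len(self.channels_per_block)} entries "
                f"for {self.n_res_blocks} blocks"
            )
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.n_classes != 4:
            raise ValueError("n_classes is fixed at 4 (NOQRS, N, PVC, PAC)")


class QrsSegmenter:
    """Residual CNN + GRU + per-position FC sequence segmenter."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks: list[ResBlock1d] = []
        c_in = 1
        for i, c_out in enumerate(config.channels_per_block):
            self.blocks.append(
                ResBlock1d(c_in, c_out, config.kernel_size, rng, f"res{i}")
            )
            c_in = c_out
        self.gru_fwd = GRU(c_in, config.gru_hidden, rng, reverse=False, prefix="gru_f")
        self.gru_bwd = (
            GRU(c_in, config.gru_hidden, rng, reverse=True, prefix="gru_b")
            if config.gru_bidirectional
            else None
        )
        fc_in = config.gru_hidden * (2 if config.gru_bidirectional else 1)
        self.fc = PositionwiseLinear(fc_in, config.n_classes, rng, "fc")

    # -- parameter access ---------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for block in self.blocks:
            out += block.params()
        out += self.gru_fwd.params()
        if self.gru_bwd is not None:
            out += self.gru_bwd.params()
        out += self.fc.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, block in enumerate(self.blocks):
            for bn, tag in ((block.bn1, "bn1"), (block.bn2, "bn2")):
                state[f"res{i}.{tag}.running_mean"] = bn.running_mean.copy()
                state[f"res{i}.{tag}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        by_name = {p.name: p for p in self.params()}
        for name, param in by_name.items():
            if name not in state:
                raise ValueError(f"checkpoint missing parameter {name}")
            if state[name].shape != param.value.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint "
                    f"{state[name].shape} vs model {param.value.shape}"
                )
            param.value[...] = state[name].astype(DTYPE)
        for i, block in enumerate(self.blocks):
            for bn, tag in ((block.bn1, "bn1"), (block.bn2, "bn2")):
                bn.running_mean[...] = state[f"res{i}.{tag}.running_mean"]
                bn.running_var[...] = state[f"res{i}.{tag}.running_var"]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, 1, L) float -> logits (B, n_classes, L)."""
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim != 3 or x.shape[1] != 1:
            raise ValueError(f"expected input (B, 1, L), got {x.shape}")
        if x.shape[2] < self.config.kernel_size:
            raise ValueError("input shorter than the convolution kernel")
        for block in self.blocks:
            x = block.forward(x, train)
        h = self.gru_fwd.forward(x, train)
        if self.gru_bwd is not None:
            h = np.concatenate([h, self.gru_bwd.forward(x, train)], axis=1)
        return self.fc.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.fc.backward(dlogits)
        if self.gru_bwd is not None:
            hdim = self.config.gru_hidden
            dx = self.gru_fwd.backward(dh[:, :hdim]) + self.gru_bwd.backward(dh[:, hdim:])
        else:
            dx = self.gru_fwd.backward(dh)
        for block in reversed(self.blocks):
            dx = block.backward(dx)


def build_model(config: ModelConfig | None = None) -> QrsSegmenter:
    """Construct the model; initialization is deterministic in config.seed."""
    return QrsSegmenter(config or ModelConfig())


def infer(model: QrsSegmenter, signal: np.ndarray) -> np.ndarray:
    """Run one standardized 100 Hz signal through the model.

    Returns a (4, L) probability mask whose columns sum to 1.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if not np.all(np.isfinite(signal)):
        raise ValueError("non-finite values in inference input")
    logits = model.forward(signal.reshape(1, 1, -1), train=False)
    return softmax(logits.astype(np.float64), axis=1)[0]


def save_model(model: QrsSegmenter, path: str | Path) -> None:
    """Checkpoint = npz archive of weights plus the config as JSON."""
    path = Path(path)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_model(path: str | Path) -> QrsSegmenter:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    if "__config__" not in state:
        raise ValueError(f"{path}: not a model checkpoint (missing config)")
    config_dict = json.loads(bytes(state.pop("__config__")).decode())
    config = ModelConfig(**config_dict)
    model = QrsSegmenter(config)
    model.load_state_dict(state)
    return model
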