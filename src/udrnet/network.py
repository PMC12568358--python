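"""The registration network: an encoder–decoder that maps a (moving, fixed)
pair to a dense displacement field, with scHAF at every skip connection.

Architecture (VoxelMorph-style U-Net):

* input: the two volumes concatenated on the channel axis (2 channels);
* each encoder level: Conv3 -> ReLU -> Conv3 -> ReLU, then MaxPool(2); the
  pre-pool features feed the matching decoder level via a skip connection;
* a bottleneck conv block at the lowest resolution;
* each decoder level: transposed 3x3x3 convolution (stride 2, doubling the
  spatial dims), skip features filtered by scHAF (or passed through raw when
  ``use_schaf`` is off — the ablation baseline), channel concatenation, then
  Conv3 -> ReLU -> Conv3 -> ReLU;
* a final 3x3x3 convolution to 3 channels (no activation) emits the DVF.

The DVF head is zero-initialized so an untrained model is exactly the
identity transform — the standard stabilization for unsupervised
registration.  With ``use_schaf=False`` the model is architecturally
identical except at skip connections and has strictly fewer parameters,
which is precisely the ablation contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ._autodiff import Tensor, concat, maxpool3d, relu
from ._nn import Conv3d, ConvTranspose3d, Module
from .core_io import DisplacementField, IntensityDomain, Volume
from .schaf import Schaf, SchafConfig
from .warp import warp_image

__all__ = ["NetworkConfig", "RegistrationModel", "predict_dvf", "register",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``levels`` encoder blocks each end in a 2x pool, so input dims must be
    divisible by ``2**levels``.  Channel widths default to VoxelMorph-like
    values and are freely configurable.
    """

    levels: int = 4
    enc_channels: tuple[int, ...] = (16, 32, 32, 32)
    dec_channels: tuple[int, ...] = (32, 32, 32, 16)
    prehead_channels: int = 16
    use_schaf: bool = True
    schaf: SchafConfig = field(default_factory=SchafConfig)
    in_channels: int = 2
    out_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if len(self.enc_channels) != self.levels or len(self.dec_channels) != self.levels:
            raise ValueError(
                f"enc/dec channel lists must have length levels={self.levels}, "
                f"got {len(self.enc_channels)}/{len(self.dec_channels)}"
            )
        if self.out_channels != 3:
            raise ValueError("out_channels is fixed at 3 (DVF components)")
        if self.in_channels != 2:
            raise ValueError("in_channels is fixed at 2 (moving + fixed)")

    @property
    def divisibility(self) -> int:
        return 2 ** self.levels

    @classmethod
    def desk_scale(cls, use_schaf: bool = True, seed: int = 0) -> "NetworkConfig":
        """A small 3-level model for 32^3 volumes on a CPU."""
        return cls(levels=3, enc_channels=(4, 8, 8), dec_channels=(8, 8, 4),
                   prehead_channels=8, use_schaf=use_schaf, seed=seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["enc_channels"] = list(self.enc_channels)
        d["dec_channels"] = list(self.dec_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        sc = d.pop("schaf", {})
        return cls(schaf=SchafConfig(**sc),
                   enc_channels=tuple(d.pop("enc_channels")),
                   dec_channels=tuple(d.pop("dec_channels")), **d)


class _ConvBlock(Module):
    """Conv3 -> ReLU -> Conv3 -> ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(c_in, c_out, kernel=3, rng=rng)
        self.conv2 = Conv3d(c_out, c_out, kernel=3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.conv2(relu(self.conv1(x))))


class RegistrationModel(Module):
    """Encoder–decoder DVF predictor; see the module docstring."""

    def __init__(self, config: NetworkConfig | None = None):
        super().__init__()
        self.config = config or NetworkConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        c = cfg.in_channels
        for i, ce in enumerate(cfg.enc_channels):
            setattr(self, f"enc{i}", _ConvBlock(c, ce, rng))
            c = ce
        self.bottleneck = _ConvBlock(c, cfg.enc_channels[-1], rng)
        c = cfg.enc_channels[-1]
        for i in reversed(range(cfg.levels)):
            cd = cfg.dec_channels[i]
            setattr(self, f"up{i}", ConvTranspose3d(c, cd, rng))
            if cfg.use_schaf:
                setattr(self, f"schaf{i}", Schaf(cfg.enc_channels[i], cfg.schaf, rng))
            setattr(self, f"dec{i}", _ConvBlock(cd + cfg.enc_channels[i], cd, rng))
            c = cd
        self.prehead = Conv3d(c, cfg.prehead_channels, kernel=3, rng=rng)
        # zero-initialized head: the untrained model is the identity transform
        self.head = Conv3d(cfg.prehead_channels, 3, kernel=3, rng=rng, zero_init=True)

    def _check_spatial(self, shape: tuple[int, ...]) -> None:
        div = self.config.divisibility
        if any(s % div for s in shape):
            raise ValueError(
                f"spatial dims {shape} must each be divisible by {div} "
                f"(levels={self.config.levels}, one 2x pool per level)"
            )

    def forward(self, x: Tensor) -> Tensor:
        """(N, 2, D, H, W) -> (N, 3, D, H, W) displacement, in voxels."""
        self._check_spatial(x.shape[2:])
        cfg = self.config
        skips = []
        for i in range(cfg.levels):
            x = getattr(self, f"enc{i}")(x)
            skips.append(x)
            x = maxpool3d(x)
        x = self.bottleneck(x)
        for i in reversed(range(cfg.levels)):
            x = getattr(self, f"up{i}")(x)
            skip = skips[i]
            if cfg.use_schaf:
                skip = getattr(self, f"schaf{i}")(skip)
            x = getattr(self, f"dec{i}")(concat([x, skip], axis=1))
        return self.head(relu(self.prehead(x)))


def _as_input(moving: Volume, fixed: Volume) -> np.ndarray:
    if moving.shape != fixed.shape:
        raise ValueError(f"moving shape {moving.shape} != fixed shape {fixed.shape}")
    for v, label in ((moving, "moving"), (fixed, "fixed")):
        if v.intensity_domain is not IntensityDomain.NORMALIZED_0_1:
            raise ValueError(
                f"{label} volume must be normalized_0_1, got {v.intensity_domain.value}"
            )
    return np.stack([moving.data, fixed.data])[None].astype(np.float32)


def predict_dvf(model: RegistrationModel, moving: Volume, fixed: Volume) -> DisplacementField:
    """Run the network on one pair and return the predicted DVF (voxels,
    defined on the fixed grid).  Inference is deterministic."""
    out = model(Tensor(_as_input(moving, fixed)))
    return DisplacementField(out.data[0])


def register(model: RegistrationModel, moving: Volume, fixed: Volume
             ) -> tuple[DisplacementField, Volume]:
    """Predict the DVF and warp the moving image with it."""
    dvf = predict_dvf(model, moving, fixed)
    return dvf, warp_image(moving, dvf, mode="trilinear")


# -- checkpoints --------------------------------------------------------------

def save_checkpoint(model: RegistrationModel, directory) -> None:
    """Write ``weights.npz`` + ``config.yaml`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.state_dict())
    (directory / "config.yaml").write_text(
        yaml.safe_dump(model.config.to_dict(), sort_keys=False)
    )


def load_checkpoint(directory) -> RegistrationModel:
    directory = Path(directory)
    cfg = NetworkConfig.from_dict(yaml.safe_load((directory / "config.yaml").read_text()))
    model = RegistrationModel(cfg)
    with np.load(directory / "weights.npz") as npz:
        model.load_state_dict(dict(npz))
    return model
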