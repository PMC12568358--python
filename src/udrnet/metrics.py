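"""Registration losses and evaluation metrics.

Evaluation metrics (NumPy, on Volumes/Masks):

* ``dice`` — 2|A∩B| / (|A| + |B|), overlap of two binary regions in [0, 1];
* ``mse`` — mean squared intensity difference (images assumed in [0, 1], so
  the result is also in [0, 1] and ``1 - MSE`` is a similarity score);
* ``ncc`` — global normalized cross-correlation in [-1, 1], invariant to
  positive affine intensity changes.  It is computed over the whole volume
  (no local windows).

Results tables conventionally print all three on a percentage scale
(Dice %, NCC %, 1-MSE %); :class:`MetricsReport` carries both raw and
percentage forms.

Training losses (autodiff Tensors, differentiable w.r.t. the warped image
and hence the DVF): ``1 - NCC`` or MSE, optionally plus a forward-difference
smoothness penalty on the DVF (off by default — the training strategy is
similarity loss alone, with NCC the default because alignment quality is
judged primarily by NCC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .core_io import DisplacementField, ImagePair, Mask, Volume
from .warp import warp_mask

__all__ = [
    "LossConfig", "MetricsReport", "dice", "mse", "ncc",
    "similarity_loss", "smoothness_loss", "evaluate_pair", "evaluate_dataset",
]


@dataclass(frozen=True)
class LossConfig:
    similarity: str = "ncc"          # "ncc" or "mse"
    lambda_smooth: float = 0.0       # weight on the optional DVF gradient penalty

    def __post_init__(self):
        if self.similarity not in ("ncc", "mse"):
            raise ValueError(f"similarity must be 'ncc' or 'mse', got {self.similarity!r}")
        if self.lambda_smooth < 0:
            raise ValueError(f"lambda_smooth must be >= 0, got {self.lambda_smooth}")


@dataclass
class MetricsReport:
    """Metrics for one registered pair, raw and on the percentage scale."""

    mse_raw: float
    one_minus_mse_pct: float
    ncc_pct: float
    dice_pct: float | None = None    # absent when masks are unavailable

    def as_dict(self) -> dict:
        return {
            "1-MSE (%)": self.one_minus_mse_pct,
            "NCC (%)": self.ncc_pct,
            "Dice (%)": self.dice_pct,
            "MSE (raw)": self.mse_raw,
        }


def _check_same_shape(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks count as perfect
    agreement (1), the limit of the 0/0 case."""
    _check_same_shape(a, b, "dice")
    na = int(a.data.sum())
    nb = int(b.data.sum())
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def mse(f: Volume, m: Volume) -> float:
    """Mean squared intensity difference."""
    _check_same_shape(f, m, "mse")
    d = np.asarray(f.data, dtype=np.float64) - np.asarray(m.data, dtype=np.float64)
    return float(np.mean(d * d))


def ncc(f: Volume, m: Volume) -> float:
    """Global normalized cross-correlation,
    sum((f-mu_f)(m-mu_m)) / sqrt(sum((f-mu_f)^2) sum((m-mu_m)^2))."""
    _check_same_shape(f, m, "ncc")
    fd = np.asarray(f.data, dtype=np.float64)
    md = np.asarray(m.data, dtype=np.float64)
    fc = fd - fd.mean()
    mc = md - md.mean()
    denom = np.sqrt((fc * fc).sum() * (mc * mc).sum())
    if denom == 0:
        raise ValueError(
            "ncc undefined: at least one image is constant (zero variance)"
        )
    return float(np.clip((fc * mc).sum() / denom, -1.0, 1.0))


# -- differentiable losses ----------------------------------------------------

def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, Volume):
        return Tensor(x.data)
    return Tensor(np.asarray(x))


def ncc_tensor(f: Tensor, w: Tensor, eps: float = 1e-8) -> Tensor:
    """NCC per batch item, averaged over the batch; differentiable."""
    axes = tuple(range(1, len(f.shape)))
    fc = f - f.mean(axis=axes, keepdims=True)
    wc = w - w.mean(axis=axes, keepdims=True)
    num = (fc * wc).sum(axis=axes)
    den = ((fc * fc).sum(axis=axes) * (wc * wc).sum(axis=axes) + eps).sqrt()
    return (num / den).mean()


def similarity_loss(f, w, cfg: LossConfig = LossConfig()) -> Tensor:
    """Dissimilarity between fixed and warped: MSE, or ``1 - NCC``.

    Accepts Volumes, arrays or Tensors; returns a scalar Tensor (call
    ``.backward()`` to differentiate w.r.t. any Tensor argument).  Both
    options are minimized, at 0, by perfect alignment.
    """
    ft, wt = _as_tensor(f), _as_tensor(w)
    if ft.shape != wt.shape:
        raise ValueError(f"similarity_loss: shape mismatch {ft.shape} vs {wt.shape}")
    if cfg.similarity == "mse":
        d = ft - wt
        return (d * d).mean()
    if len(ft.shape) == 3:  # single volume: add a batch axis
        ft = ft.reshape(1, *ft.shape)
        wt = wt.reshape(1, *wt.shape)
    return 1.0 - ncc_tensor(ft, wt)


def smoothness_loss(dvf) -> Tensor:
    """Mean squared forward-difference gradient of each DVF component over
    all spatial axes (zero for any constant field, i.e. pure translation)."""
    if isinstance(dvf, DisplacementField):
        t = Tensor(dvf.data)
    else:
        t = _as_tensor(dvf)
    nd = len(t.shape)
    spatial = range(nd - 3, nd)
    total = None
    for ax in spatial:

        def sl(lo, hi):
            idx = [slice(None)] * nd
            idx[ax] = slice(lo, hi)
            return tuple(idx)

        d = _slice_tensor(t, sl(1, None)) - _slice_tensor(t, sl(None, -1))
        term = (d * d).mean()
        total = term if total is None else total + term
    return total


def _slice_tensor(t: Tensor, idx) -> Tensor:
    def bw(g):
        full = np.zeros_like(t.data)
        full[idx] = g
        t._accum(full)

    return Tensor._from_op(t.data[idx], (t,), bw)


# -- pair / dataset evaluation ------------------------------------------------

def evaluate_pair(model, pair: ImagePair) -> MetricsReport:
    """Register a pair and report the three metrics on the percentage scale.

    Dice compares the fixed mask with the moving mask carried through the
    predicted DVF; it is reported as ``None`` when either mask is missing.
    """
    from .network import register  # local import to avoid a cycle

    dvf, warped = register(model, pair.moving, pair.fixed)
    m = mse(pair.fixed, warped)
    n = ncc(pair.fixed, warped)
    d_pct = None
    if pair.fixed_mask is not None and pair.moving_mask is not None:
        d_pct = 100.0 * dice(pair.fixed_mask, warp_mask(pair.moving_mask, dvf))
    return MetricsReport(mse_raw=m, one_minus_mse_pct=100.0 * (1.0 - m),
                         ncc_pct=100.0 * n, dice_pct=d_pct)


def evaluate_dataset(model, pairs: list[ImagePair], top_k: int | None = None):
    """Evaluate every pair; returns a pandas DataFrame (one row per pair)
    plus a mean row.  ``top_k`` adds a mean over the k best pairs by NCC,
    mirroring a "(TOP k)" reporting convention."""
    import pandas as pd

    rows = []
    for pair in pairs:
        rep = evaluate_pair(model, pair)
        rows.append({"pair": pair.name, **rep.as_dict()})
    df = pd.DataFrame(rows).set_index("pair")
    summary = df.mean(numeric_only=True).to_frame("mean").T
    if top_k is not None:
        top = df.nlargest(top_k, "NCC (%)").mean(numeric_only=True)
        summary.loc[f"mean (TOP {top_k})"] = top
    return df, summary
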