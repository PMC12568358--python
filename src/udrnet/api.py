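"""High-level modelling interface: build a registration model from data,
fit it, and inspect results.

``UnsupervisedRegistration`` bundles a dataset of image pairs with a network
and training configuration; ``fit()`` runs the unsupervised loop and returns
a :class:`RegistrationResults` carrying the trained model, the loss history,
per-pair test metrics and a ``summary()`` table.  This mirrors the
model/results idiom of statistical modelling libraries; the functional
modules (``network``, ``training``, ``metrics``, ...) remain available for
piecemeal use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ImagePair
from .metrics import MetricsReport, evaluate_dataset, evaluate_pair
from .network import NetworkConfig, RegistrationModel, register, save_checkpoint
from .training import TrainConfig, TrainHistory, train

__all__ = ["UnsupervisedRegistration", "RegistrationResults"]


class UnsupervisedRegistration:
    """An unsupervised pairwise registration study.

    Parameters
    ----------
    train_pairs, test_pairs
        Image pairs (``normalized_0_1`` intensities).  Test pairs provide
        the early-stopping signal and the reported metrics.
    network
        Architecture configuration; defaults to the full-scale network.
    train_config
        Optimization protocol; defaults to the reference protocol
        (Adam 1e-5, 150 epochs, batch 16, patience 5, seed 666).
    """

    def __init__(self, train_pairs: list[ImagePair], test_pairs: list[ImagePair],
                 network: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not train_pairs:
            raise ValueError("train_pairs must be nonempty")
        self.train_pairs = list(train_pairs)
        self.test_pairs = list(test_pairs)
        self.network = network or NetworkConfig()
        self.train_config = train_config or TrainConfig()

    def baseline_metrics(self) -> pd.DataFrame:
        """Pre-registration metrics of the raw test pairs.

        An untrained model has a zero-initialized DVF head, i.e. it is the
        identity transform, so evaluating it reports the alignment of the
        pairs as given."""
        df, _ = evaluate_dataset(RegistrationModel(self.network), self.test_pairs)
        return df

    def fit(self, log_fn=None) -> "RegistrationResults":
        model = RegistrationModel(self.network)
        model, history = train(model, self.train_pairs, self.test_pairs,
                               self.train_config, log_fn=log_fn)
        per_pair, summary = evaluate_dataset(model, self.test_pairs)
        return RegistrationResults(model=self, fitted=model, history=history,
                                   per_pair=per_pair, summary_table=summary)


@dataclass
class RegistrationResults:
    """Results of a fitted registration study."""

    model: UnsupervisedRegistration
    fitted: RegistrationModel
    history: TrainHistory
    per_pair: pd.DataFrame
    summary_table: pd.DataFrame
    _baseline: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def baseline(self) -> pd.DataFrame:
        if self._baseline is None:
            self._baseline = self.model.baseline_metrics()
        return self._baseline

    def register_pair(self, pair: ImagePair):
        """Predicted DVF and warped moving image for one pair."""
        return register(self.fitted, pair.moving, pair.fixed)

    def evaluate_pair(self, pair: ImagePair) -> MetricsReport:
        return evaluate_pair(self.fitted, pair)

    def summary(self) -> str:
        h = self.history
        lines = [
            "Unsupervised deformable registration — fit summary",
            "=" * 52,
            f"epochs run:        {h.stop_epoch}"
            + ("  (stopped early)" if h.stopped_early else ""),
            f"best epoch:        {h.best_epoch} (test loss {h.best_test_loss:.5f})",
            f"final train loss:  {h.train_loss[-1]:.5f}",
            f"parameters:        {self.fitted.n_parameters()}",
            "",
            "Test-set metrics (mean over pairs):",
            self.summary_table.round(3).to_string(),
            "",
            "Pre-registration baseline (identity transform):",
            self.baseline.mean(numeric_only=True).round(3).to_frame("mean").T.to_string(),
        ]
        return "\n".join(lines)

    def save(self, directory) -> None:
        save_checkpoint(self.fitted, directory)

    def plot_history(self, path=None):
        """Train/test loss curves; returns the matplotlib figure."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        epochs = np.arange(1, len(self.history.train_loss) + 1)
        ax.plot(epochs, self.history.train_loss, label="train loss")
        ax.plot(epochs, self.history.test_loss, label="test loss")
        ax.axvline(self.history.best_epoch, ls="--", lw=0.8, c="grey")
        ax.set_xlabel("epoch")
        ax.set_ylabel("similarity loss")
        ax.legend(frameon=False)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
        return fig
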