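"""Model/results interface over the imbalance-aware AutoML search.

:class:`ImbalancedAutoML` is built from a feature matrix and binary labels
(or a labelled DataFrame); its :meth:`~ImbalancedAutoML.fit` runs one or
more TPE optimization rounds and returns an :class:`AutoMLResults` carrying
the winning pipeline configuration, the per-round CV1/CV2 objectives, the
full trial log, and a ``summary()`` table.  Convergence plotting and final
model refitting hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import Calibrator, fit_calibrator
from .losses import train_boosted_classifier
from .sampling import apply_sampling, effective_fraction
from .search import (
    PipelineConfig,
    RoundResult,
    RoundsReport,
    default_search_space,
    run_rounds,
)


class ImbalancedAutoML:
    """Joint search over resampling, cost-sensitive loss, calibration and
    booster hyperparameters for an imbalanced binary outcome.

    Parameters
    ----------
    X : array-like, shape (n, d)
        Feature matrix.
    y : array-like of 0/1
        Binary labels; 1 is the (minority) positive class.
    n_folds : int
        Folds of the stratified CV (3 train / 1 calibration / 1 test roles).
    space : list, optional
        Search-space override; defaults to the full joint space with the
        sampling fraction anchored at this dataset's imbalance.
    """

    def __init__(self, X, y, n_folds: int = 5, space: list | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        self.n_folds = n_folds
        self.minority_fraction = effective_fraction(self.y)
        self.space = space if space is not None else default_search_space(self.minority_fraction)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", **kwargs
    ) -> "ImbalancedAutoML":
        feats = [c for c in df.columns if c != label_col]
        return cls(df[feats].to_numpy(dtype=float), df[label_col].to_numpy(), **kwargs)

    def fit(
        self,
        n_iter: int = 500,
        n_rounds: int = 1,
        seed: int = 0,
        **kwargs,
    ) -> "AutoMLResults":
        """Run the optimization and return the results object."""
        report = run_rounds(
            self.X,
            self.y,
            n_rounds=n_rounds,
            n_iter=n_iter,
            seed=seed,
            k=self.n_folds,
            space=self.space,
            **kwargs,
        )
        return AutoMLResults(self, report)


class AutoMLResults:
    """Fitted search results: winners, objectives, diagnostics."""

    def __init__(self, model: ImbalancedAutoML, report: RoundsReport):
        self.model = model
        self.report = report
        self.rounds: list[RoundResult] = report.rounds
        best_idx = int(
            np.argmax([r.cv1_objective for r in report.rounds])
        )
        self.best_round: RoundResult = report.rounds[best_idx]
        self.best_config: PipelineConfig = self.best_round.best_config

    # -- headline numbers ---------------------------------------------------
    @property
    def cv1_objective(self) -> float:
        """Best search-time mean test AUPRC."""
        return self.best_round.cv1_objective

    @property
    def cv2_metrics(self):
        """Mean re-evaluation metrics of every round's winner."""
        return self.report.mean_cv2

    def per_round_table(self) -> pd.DataFrame:
        return self.report.per_round_table()

    def trial_log(self) -> pd.DataFrame:
        rows = []
        for rnd, r in enumerate(self.rounds, start=1):
            for t in r.trials:
                rows.append(
                    {
                        "round": rnd,
                        "iteration": t.iteration,
                        "objective": t.objective,
                        "sampler": t.config.sampler.method,
                        "loss": t.config.loss.kind,
                        "calibration": t.config.calibration,
                    }
                )
        return pd.DataFrame(rows)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary of the search outcome."""
        c = self.best_config
        m = self.cv2_metrics
        lines = [
            "Imbalance-aware AutoML results",
            "=" * 46,
            f"Samples / features     {self.model.X.shape[0]} / {self.model.X.shape[1]}",
            f"Minority fraction      {self.model.minority_fraction:.4f} "
            f"(1:{1 / self.model.minority_fraction:.1f})",
            f"Rounds x iterations    {len(self.rounds)} x {len(self.rounds[0].trials)}",
            "-" * 46,
            "Best configuration (by CV1 AUPRC)",
            f"  sampler              {c.sampler.method}"
            + (
                f" (fraction {c.sampler.sampling_fraction:.3f})"
                if c.sampler.sampling_fraction is not None and c.sampler.applicable
                else ""
            ),
            f"  loss                 {c.loss.kind} (w = {c.loss.weight:.2f}"
            + (f", gamma = {c.loss.focal_gamma:.2f})" if c.loss.focal_gamma is not None else ")"),
            f"  calibration          {c.calibration}",
            f"  booster              n_estimators={c.booster.n_estimators}, "
            f"max_depth={c.booster.max_depth}, lr={c.booster.learning_rate:.2f},",
            f"                       subsample={c.booster.subsample:.2f}, "
            f"colsample={c.booster.colsample_bytree:.2f}",
            "-" * 46,
            f"CV1 objective (AUPRC)  {self.cv1_objective:.4f}",
            f"CV2 mean AUPRC         {m.auprc:.4f}",
            f"CV2 mean precision     {m.precision:.4f}",
            f"CV2 mean recall        {m.recall:.4f}",
            f"CV2 mean F1            {m.f1:.4f}",
            f"CV2 mean ECE           {m.ece:.4f}",
        ]
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Running-best CV1 objective per iteration, one line per round."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, r in enumerate(self.rounds, start=1):
            ax.plot(r.running_best(), label=f"round {i}")
        ax.set_xlabel("iteration")
        ax.set_ylabel("running best mean AUPRC (CV1)")
        ax.legend()
        return ax

    def refit(self, seed: int = 0):
        """Refit the winning pipeline on the full dataset.

        Returns ``(model, calibrator)``.  Note the calibrator is fitted
        in-sample here; for honest probabilities reserve a calibration split.
        """
        c = self.best_config
        Xr, yr = apply_sampling(self.model.X, self.model.y, c.sampler, seed=seed)
        model = train_boosted_classifier(Xr, yr, c.loss, c.booster, seed=seed)
        calibrator = fit_calibrator(
            c.calibration, model.predict_proba(self.model.X), self.model.y
        )
        return model, calibrator
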