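"""Top-level modelling interface.

`EmotionRecognitionModel` bundles a flight cohort with a pipeline
configuration; `fit()` runs the leave-one-flight-out training/evaluation and
returns `LOOCVResults`, which carries per-fold per-emotion errors, their
cohort means ± standard deviations, the match-accuracy counts, and a
printable `summary()` table.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .evaluate import EvalReport, PipelineConfig, loocv
from .session import EMOTIONS, FlightSession
from .synth import SynthConfig, generate_cohort


class EmotionRecognitionModel:
    """Leave-one-flight-out emotion-intensity regression model."""

    def __init__(
        self, cohort: list[FlightSession], config: PipelineConfig | None = None
    ):
        if len(cohort) < 2:
            raise ValueError("need at least 2 sessions")
        self.cohort = cohort
        self.config = config or PipelineConfig()

    @classmethod
    def from_synthetic(
        cls,
        synth_config: SynthConfig | None = None,
        config: PipelineConfig | None = None,
    ) -> "EmotionRecognitionModel":
        """Build from a freshly generated synthetic cohort."""
        return cls(generate_cohort(synth_config or SynthConfig()), config)

    def fit(self) -> "LOOCVResults":
        report = loocv(self.cohort, self.config)
        return LOOCVResults(self, report)


class LOOCVResults:
    """Fitted-evaluation results: estimates, dispersions, diagnostics."""

    def __init__(self, model: EmotionRecognitionModel, report: EvalReport):
        self.model = model
        self.report = report

    @property
    def n_folds(self) -> int:
        return len(self.report.folds)

    @property
    def fold_frame(self) -> pd.DataFrame:
        return self.report.to_frame()

    @property
    def mean_rmse(self) -> dict[str, float]:
        return self.report.mean_rmse()

    @property
    def mean_mae(self) -> dict[str, float]:
        return self.report.mean_mae()

    @property
    def mean_match_accuracy(self) -> float:
        return self.report.mean_match_accuracy()

    def summary(self) -> str:
        """Tables 4/5-style text summary: per-fold rows, mean ± sd footer."""
        df = self.fold_frame
        lines = ["Leave-one-flight-out emotion recognition", "=" * 72]
        header = f"{'session':>8}" + "".join(
            f"{e[:4].upper():>8}" for e in EMOTIONS
        ) + f"{'match%':>9}"
        lines.append("per-emotion RMSE (and match accuracy)")
        lines.append(header)
        for sid, row in df.iterrows():
            lines.append(
                f"{sid:>8}"
                + "".join(f"{row[f'rmse_{e}']:>8.3f}" for e in EMOTIONS)
                + f"{100 * row['match_accuracy']:>8.2f} "
                f"({int(row['matched'])}/{int(row['total'])})"
            )
        mean_r = self.mean_rmse
        sd_r = self.report.sd_rmse()
        lines.append("-" * 72)
        lines.append(
            f"{'mean±sd':>8}"
            + "".join(f"{mean_r[e]:>8.3f}" for e in EMOTIONS)
            + f"{100 * self.mean_match_accuracy:>8.2f}%"
        )
        lines.append(
            f"{'± sd':>8}" + "".join(f"{sd_r[e]:>8.3f}" for e in EMOTIONS)
        )
        lines.append("-" * 72)
        mean_m = self.mean_mae
        lines.append(
            "mean MAE "
            + "  ".join(f"{e}={mean_m[e]:.3f}" for e in EMOTIONS)
        )
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report.summary_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        self.fold_frame.to_csv(path)

    def plot_errors(self, ax=None):
        """Bar chart of cohort-mean RMSE and MAE per emotion."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(EMOTIONS))
        w = 0.38
        ax.bar(x - w / 2, [self.mean_rmse[e] for e in EMOTIONS], w, label="RMSE")
        ax.bar(x + w / 2, [self.mean_mae[e] for e in EMOTIONS], w, label="MAE")
        ax.set_xticks(x, EMOTIONS)
        ax.set_ylabel("error (intensity units)")
        ax.legend()
        return ax
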