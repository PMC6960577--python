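"""SVD-based per-block dimensionality reduction.

Each modality block of the feature matrix is column-centered and factorized
as A = U D V*. Features are then ranked by the norm of their loadings in the
leading right singular directions, weighted by the singular values, and the
top-``count`` *original* columns are retained — dimensionality reduction
that preserves feature identities. Default retained counts: 6 HR, 4 GSR and
5 per EEG channel (40), i.e. 50 of the 90 features. A projection mode
(truncated scores U·D) is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix

DEFAULT_COUNTS = {"hr": 6, "gsr": 4, "eeg_per_channel": 5}


def svd_decompose(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD ``A = U D V*`` with singular values sorted descending."""
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or min(A.shape) < 1:
        raise ValueError("matrix must be 2-D and non-empty")
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite entries in matrix")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    return U, s, Vt


@dataclass
class SvdReduction:
    """Fitted per-block selection: rankings, scores and retained columns."""

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    mode: str = "select"  # or "project"
    singular_values_: dict[str, np.ndarray] = field(default_factory=dict)
    importance_: dict[str, pd.Series] = field(default_factory=dict)
    selected_columns_: list[str] = field(default_factory=list)
    column_means_: pd.Series | None = None
    components_: dict[str, np.ndarray] = field(default_factory=dict)  # V* rows

    def _block_count(self, block: str) -> int:
        if block.startswith("eeg:"):
            return self.counts.get("eeg_per_channel", 5)
        return self.counts.get(block, 0)

    def fit(self, fm: FeatureMatrix) -> "SvdReduction":
        """Rank and choose columns per block from the (training) matrix."""
        self.column_means_ = fm.X.mean(axis=0)
        self.singular_values_.clear()
        self.importance_.clear()
        selected: list[str] = []
        for block in fm.blocks:
            cols = fm.block_columns(block)
            count = self._block_count(block)
            if count > len(cols):
                raise ValueError(
                    f"requested {count} features from block {block!r} "
                    f"of width {len(cols)}"
                )
            A = fm.X[cols].to_numpy() - self.column_means_[cols].to_numpy()
            _, s, Vt = svd_decompose(A)
            self.singular_values_[block] = s
            r = min(count, len(s))
            self.components_[block] = Vt[:r, :]
            # importance of original column j: ‖(s_k V*[k,j])_{k<r}‖
            load = np.sqrt(np.sum((s[:r, None] * Vt[:r, :]) ** 2, axis=0))
            imp = pd.Series(load, index=cols)
            self.importance_[block] = imp
            # stable ranking: score descending, original column order breaks ties
            order = sorted(range(len(cols)), key=lambda j: (-load[j], j))
            keep = sorted(order[:count])  # preserve original column order
            selected.extend([cols[j] for j in keep])
        self.selected_columns_ = selected
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if not self.selected_columns_:
            raise ValueError("SvdReduction is not fitted")
        if self.mode == "select":
            return FeatureMatrix(
                fm.X[self.selected_columns_].copy(), fm.y.copy(), mode="selected"
            )
        # projection mode: per-block truncated scores U·D = A_centered·Vᵣᵀ,
        # using the components fitted on the training matrix
        parts = []
        for block, Vr in self.components_.items():
            cols = list(self.importance_[block].index)
            A = fm.X[cols].to_numpy() - self.column_means_[cols].to_numpy()
            scores = A @ Vr.T
            names = [
                f"{block.replace(':', '_')}_svd{k}" for k in range(scores.shape[1])
            ]
            parts.append(pd.DataFrame(scores, index=fm.X.index, columns=names))
        return FeatureMatrix(pd.concat(parts, axis=1), fm.y.copy(), mode="projected")

    def manifest(self) -> pd.DataFrame:
        """Per-feature selection manifest: block, score, kept flag."""
        rows = []
        for block, imp in self.importance_.items():
            for name, score in imp.items():
                rows.append(
                    {
                        "block": block,
                        "feature": name,
                        "importance": score,
                        "kept": name in self.selected_columns_,
                    }
                )
        return pd.DataFrame(rows)


def select_features(
    fm: FeatureMatrix,
    counts: dict[str, int] | None = None,
    mode: str = "select",
) -> FeatureMatrix:
    """Fit-and-transform convenience for a single matrix."""
    red = SvdReduction(counts=dict(counts or DEFAULT_COUNTS), mode=mode)
    return red.fit(fm).transform(fm)
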