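"""Shared in-memory containers for feature-space learning.

A :class:`LabeledDomain` is the unit every learning stage consumes and
produces: a ``(n_samples, n_features)`` matrix of band-power (or other)
features with optional binary labels aligned to its rows.  In transfer
terminology, the pooled training subjects form the *source domain* and the
held-out subject the *target domain*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LabeledDomain:
    """A feature matrix with (optionally) per-row integer class labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Feature matrix; must be finite.
    y : ndarray of shape (n_samples,), optional
        Integer class labels in ``{0, .., C-1}`` aligned with rows of ``X``.
        ``None`` for an unlabeled domain.
    """

    X: np.ndarray
    y: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape != (self.X.shape[0],):
                raise ValueError(
                    f"y has shape {self.y.shape}, expected ({self.X.shape[0]},)"
                )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        if self.y is None:
            raise ValueError("domain is unlabeled")
        return np.unique(self.y)
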