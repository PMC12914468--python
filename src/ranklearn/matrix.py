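"""Core data containers.

An :class:`ExpressionMatrix` holds a samples x features intensity table with
binary class labels and an explicit missing-value mask; a :class:`RankProfile`
is a permutation of feature ranks — the learned model artifact; a
:class:`SimilarityResult` bundles per-sample similarity scores with the
group-contrast objective (TSS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RankProfile", "ExpressionMatrix", "SimilarityResult"]


@dataclass(frozen=True)
class RankProfile:
    """A feature rank profile: a permutation of ``{1, ..., p}``.

    ``order[i]`` is the rank assigned to feature ``i`` (0-based feature
    index, 1-based ranks). A sample whose observed intensities are ordered
    like the profile's ranks scores maximally case-like.
    """

    order: np.ndarray

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=np.int64)
        object.__setattr__(self, "order", order)
        p = order.size
        if p < 2:
            raise ValueError("a rank profile needs at least two features")
        if not np.array_equal(np.sort(order), np.arange(1, p + 1)):
            raise ValueError("order must be a permutation of 1..p")

    @property
    def p(self) -> int:
        return int(self.order.size)

    @classmethod
    def identity(cls, p: int) -> "RankProfile":
        return cls(np.arange(1, p + 1))

    @classmethod
    def random(cls, p: int, rng: np.random.Generator) -> "RankProfile":
        return cls(rng.permutation(p) + 1)

    def swap(self, i: int, j: int) -> "RankProfile":
        """Profile with the ranks of features ``i`` and ``j`` exchanged."""
        order = self.order.copy()
        order[i], order[j] = order[j], order[i]
        return RankProfile(order)

    def reversed(self) -> "RankProfile":
        """Profile with every rank r mapped to p + 1 - r."""
        return RankProfile(self.p + 1 - self.order)


@dataclass
class ExpressionMatrix:
    """Samples x features matrix with binary labels and a missing mask.

    ``labels`` are 1 for cases and 0 for controls. Missing entries are
    flagged in ``missing_mask`` and carry NaN in ``values``; any non-finite
    input value is coerced to missing with a warning.
    """

    values: np.ndarray
    labels: np.ndarray
    missing_mask: np.ndarray = None
    feature_ids: list[str] = None
    sample_ids: list[str] = None

    def __post_init__(self) -> None:
        values = np.array(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features array")
        labels = np.asarray(self.labels, dtype=np.int64)
        n, p = values.shape
        if labels.shape != (n,):
            raise ValueError(f"labels must have length {n}, got {labels.shape}")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (1 = case, 0 = control)")

        if self.missing_mask is None:
            mask = ~np.isfinite(values)
        else:
            mask = np.asarray(self.missing_mask, dtype=bool).copy()
            if mask.shape != values.shape:
                raise ValueError("missing_mask shape must match values")
            nonfinite = ~np.isfinite(values) & ~mask
            if nonfinite.any():
                warnings.warn(
                    f"coerced {int(nonfinite.sum())} non-finite value(s) to missing",
                    stacklevel=2,
                )
                mask |= nonfinite
        values[mask] = np.nan

        if self.feature_ids is None:
            feature_ids = [f"f{i + 1}" for i in range(p)]
        else:
            feature_ids = [str(f) for f in self.feature_ids]
            if len(feature_ids) != p:
                raise ValueError("feature_ids length must equal feature count")
            if len(set(feature_ids)) != p:
                raise ValueError("feature_ids must be unique")
        if self.sample_ids is None:
            sample_ids = [f"s{i + 1}" for i in range(n)]
        else:
            sample_ids = [str(s) for s in self.sample_ids]
            if len(sample_ids) != n:
                raise ValueError("sample_ids length must equal sample count")

        self.values = values
        self.labels = labels
        self.missing_mask = mask
        self.feature_ids = feature_ids
        self.sample_ids = sample_ids

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == 1

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.case_mask).sum())

    def require_both_classes(self, name: str = "input") -> None:
        if self.n_cases == 0:
            raise ValueError(f"{name} contains no cases (label 1)")
        if self.n_controls == 0:
            raise ValueError(f"{name} contains no controls (label 0)")

    def subset(self, rows: np.ndarray) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            values=self.values[rows],
            labels=self.labels[rows],
            missing_mask=self.missing_mask[rows],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(rows)],
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            labels=self.labels.copy(),
            missing_mask=self.missing_mask.copy(),
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
        )


@dataclass(frozen=True)
class SimilarityResult:
    """Per-sample similarity scores and the total similarity score (TSS).

    ``tss = u_cases - u_controls``: mean similarity of cases with the
    profile minus mean similarity of controls — the search objective.
    """

    per_sample: np.ndarray
    u_cases: float
    u_controls: float
    tss: float
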