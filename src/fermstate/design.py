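"""Correlation-minimized Latin-hypercube calibration designs.

Calibration samples for the spectroscopic models are laid out over the
(Glu, Xyl, EtOH) concentration box with a Latin hypercube so every
sample carries similar leverage; many randomized candidates are ranked
by their average pairwise Pearson correlation and the least correlated
design is kept, so the regression sees three nearly independent factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DesignSpace", "Design", "lh_candidate", "avg_pairwise_pcc", "select_design"]

#: Default calibration box, g/L (lower, upper) per analyte.
DEFAULT_SPACE_BOUNDS = {"glu": (0.0, 40.0), "xyl": (0.0, 25.0), "etoh": (2.5, 32.5)}


@dataclass(frozen=True)
class DesignSpace:
    """Axis-aligned concentration box, one (lower, upper) pair per analyte."""

    bounds: dict

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name!r} must satisfy lower < upper")

    @classmethod
    def default(cls) -> "DesignSpace":
        return cls(bounds=dict(DEFAULT_SPACE_BOUNDS))

    @property
    def names(self) -> tuple:
        return tuple(self.bounds)


@dataclass(frozen=True)
class Design:
    """An n x k concentration matrix with its correlation score."""

    space: DesignSpace
    samples: np.ndarray
    score: float

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.samples, columns=list(self.space.names))
        df.insert(0, "sample", np.arange(1, len(df) + 1))
        return df


def _lh_matrix(space: DesignSpace, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for lo, hi in space.bounds.values():
        strata = rng.permutation(n_samples)
        jitter = rng.uniform(size=n_samples)
        cols.append(lo + (strata + jitter) * (hi - lo) / n_samples)
    return np.column_stack(cols)


def avg_pairwise_pcc(samples: np.ndarray) -> float:
    """Mean absolute Pearson correlation over all column pairs.

    Absolute values are used: a strong negative correlation degrades a
    calibration design just as much as a positive one.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    corr = np.corrcoef(samples, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    return float(np.mean(np.abs(corr[iu])))


def lh_candidate(space: DesignSpace, n_samples: int, seed) -> Design:
    """One randomized Latin-hypercube draw: per analyte, one uniform draw
    in each of ``n_samples`` equal-width strata, independently permuted."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    samples = _lh_matrix(space, n_samples, rng)
    score = avg_pairwise_pcc(samples) if n_samples >= 3 else float("nan")
    return Design(space=space, samples=samples, score=score)


def select_design(
    space: DesignSpace,
    n_samples: int,
    n_candidates: int = 100_000,
    seed: int | None = None,
) -> Design:
    """Generate ``n_candidates`` LH designs and keep the least correlated.

    Candidate i is drawn from the i-th spawn of the seed sequence, so the
    candidate stream is a prefix: growing ``n_candidates`` with the same
    seed can only improve (never worsen) the selected score.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    root = np.random.SeedSequence(seed)
    best: Design | None = None
    for child in root.spawn(n_candidates):
        rng = np.random.default_rng(child)
        samples = _lh_matrix(space, n_samples, rng)
        score = avg_pairwise_pcc(samples) if n_samples >= 3 else float("nan")
        if best is None or score < best.score:
            best = Design(space=space, samples=samples, score=score)
    assert best is not None
    return best
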