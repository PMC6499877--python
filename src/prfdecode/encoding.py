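"""Encoding analysis: predict voxel patterns from physical letters through
the pRF model and test geometric specificity with a 3/-1/-1/-1 contrast.

For each imagined letter the observed average imagery pattern is regressed
(OLS, with intercept) on the four predicted patterns; the per-subject
contrast places weight +3 on the matching physical letter's beta and -1 on
each of the others, and a one-sample t test across subjects evaluates it
against zero, Bonferroni-corrected for the 4-letter x 3-ROI family
(alpha_c = 0.05/12 = 0.0042).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .patterns import VoxelPattern, znormalize_pattern
from .prf import EncodingMatrix
from .stimuli import LETTERS, LetterImage, vectorize_image

#: contrast weights over (target, others); sums to zero by construction
CONTRAST_WEIGHTS = (3.0, -1.0, -1.0, -1.0)
assert abs(sum(CONTRAST_WEIGHTS)) == 0.0

MAX_CONDITION_NUMBER = 1e8


def predict_pattern(W: EncodingMatrix, letter: LetterImage) -> VoxelPattern:
    """Predicted voxel pattern W_pRF @ vec(letter), z-scored across voxels."""
    if letter.grid != W.grid:
        raise ValueError(
            f"grid mismatch: letter on {letter.grid}, encoding matrix on {W.grid}"
        )
    drive = W.W @ vectorize_image(letter).astype(float)
    return VoxelPattern(
        values=znormalize_pattern(drive),
        letter=letter.letter,
        condition="predicted",
        kind="average",
    )


def predicted_design(W: EncodingMatrix, letters: dict[str, LetterImage]) -> np.ndarray:
    """(v, 4) matrix of predicted patterns in canonical letter order."""
    return np.column_stack(
        [predict_pattern(W, letters[L]).values for L in LETTERS]
    )


def fit_letter_regression(
    observed: np.ndarray | VoxelPattern, predictors: np.ndarray
) -> np.ndarray:
    """OLS betas (4,) of one observed pattern on the 4 predicted patterns.

    ``predictors`` is (v, 4) in canonical letter order; an intercept is
    included but not returned. Collinear predictors are rejected.
    """
    y = observed.values if isinstance(observed, VoxelPattern) else np.asarray(observed)
    P = np.asarray(predictors, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(LETTERS):
        raise ValueError("predictors must be (v, 4)")
    if y.size != P.shape[0]:
        raise ValueError("observed pattern and predictors disagree on voxel count")
    if y.size < 5:
        raise ValueError("need at least 5 voxels")
    cond = np.linalg.cond(P - P.mean(axis=0))
    if cond > MAX_CONDITION_NUMBER:
        raise ValueError(f"predictors are collinear (condition number {cond:.3g})")
    model = sm.OLS(y, sm.add_constant(P)).fit()
    return model.params[1:]


@dataclass
class ContrastResult:
    """Across-subject test of one (imagined letter, ROI) contrast."""

    letter: str
    roi: str
    contrasts: np.ndarray  # per-subject contrast values
    t: float
    p: float
    corrected_alpha: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p < self.corrected_alpha


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = 12) -> float:
    """Corrected per-test alpha for the letter x ROI family."""
    return family_alpha / n_tests


def contrast_test(
    betas: np.ndarray,
    target_letter: str,
    roi: str = "",
    family_alpha: float = 0.05,
    n_tests: int = 12,
) -> ContrastResult:
    """One-sample t test of the target-vs-rest contrast across subjects.

    ``betas`` is (n_subjects, 4) in canonical letter order. The contrast is
    3*beta_target - sum(other betas); zero across-subject variance yields a
    degenerate (flagged) result rather than an undefined t.
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    if betas.shape[0] < 3:
        raise ValueError("need at least 3 subjects for the contrast test")
    if betas.shape[1] != len(LETTERS):
        raise ValueError("betas must have one column per letter")
    if target_letter not in LETTERS:
        raise ValueError(f"unknown letter {target_letter!r}")
    ti = LETTERS.index(target_letter)
    w = np.full(len(LETTERS), -1.0)
    w[ti] = 3.0
    c = betas @ w
    alpha_c = bonferroni_alpha(family_alpha, n_tests)
    if np.ptp(c) == 0:
        return ContrastResult(
            letter=target_letter, roi=roi, contrasts=c,
            t=np.nan, p=np.nan, corrected_alpha=alpha_c, degenerate=True,
        )
    t, p = stats.ttest_1samp(c, 0.0, alternative="greater")
    return ContrastResult(
        letter=target_letter, roi=roi, contrasts=c,
        t=float(t), p=float(p), corrected_alpha=alpha_c,
    )
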