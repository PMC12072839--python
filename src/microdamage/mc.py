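"""Monte Carlo point-classification estimation of the microdamage coefficient.

The microdamage coefficient of a cross-section is the fraction of the
object's area occupied by internal cracks. It is estimated by the
classical point-counting scheme: throw N uniform random points at the
section, keep only those landing on the object (points on the
background are rejected and regenerated, and do not count toward N),
and assign each accepted point i a score

    xi_i = 0    inside a crack (damage),
    xi_i = 0.5  on the crack boundary,
    xi_i = 1    in solid material.

The per-section coefficient is

    K_md_i = 1 - (sum_i xi_i) / N,

the specimen-level coefficient is the arithmetic mean of K_md_i over the
J sections (J = 20: ten horizontal plus ten vertical), and the precision
of a section estimate follows the normal approximation

    |K_md_i - truth| < x_beta * sqrt(D_xi / N),
    D_xi = mean(xi^2) - mean(xi)^2,

with x_beta the two-sided standard-normal quantile (1.96 at beta = 0.95).
N defaults to 3400 points per section.

Because accepted points are uniform over the object pixels, the
estimator is exactly unbiased for the weighted pixel-area fraction
(damage + boundary/2) / object — the quantity ``exact_damage_fraction``
computes by brute-force counting, used throughout as the oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .errors import (DegenerateMaskError, EmptyDomainError, ParameterError)
from .labels import BACKGROUND, BOUNDARY, DAMAGE, SOLID
from .phantom import exact_damage_fraction

DEFAULT_N_POINTS = 3400
DEFAULT_CONFIDENCE = 0.95


class PointSample(NamedTuple):
    """One accepted sample: continuous coordinates and its xi score."""

    x: float  # column coordinate
    y: float  # row coordinate
    xi: float  # 0, 0.5 or 1


class PointSet(Sequence):
    """Column-oriented collection of accepted point samples."""

    def __init__(self, x: np.ndarray, y: np.ndarray, xi: np.ndarray):
        self.x = np.asarray(x, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        self.xi = np.asarray(xi, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.xi)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return PointSet(self.x[i], self.y[i], self.xi[i])
        return PointSample(float(self.x[i]), float(self.y[i]), float(self.xi[i]))


def normal_quantile(confidence_level: float) -> float:
    """Two-sided standard-normal quantile x_beta.

    The value whose standard-normal CDF is (1 + beta) / 2; 1.96 at
    beta = 0.95, and -> 0 as beta -> 0.
    """
    if not (0 < confidence_level < 1):
        raise ParameterError(f"confidence level {confidence_level} outside (0, 1)")
    return float(norm.ppf((1.0 + confidence_level) / 2.0))


def classify_point(mask: np.ndarray, x: float, y: float) -> float:
    """xi score of the pixel containing the real-valued point (x, y).

    The point lies in pixel (floor(y), floor(x)). Callers must reject
    background points before classification.
    """
    mask = np.asarray(mask)
    r, c = int(np.floor(y)), int(np.floor(x))
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        raise ParameterError(f"point ({x}, {y}) outside the image")
    label = mask[r, c]
    if label == BACKGROUND:
        raise ParameterError(f"point ({x}, {y}) lies on background")
    return {SOLID: 1.0, DAMAGE: 0.0, BOUNDARY: 0.5}[int(label)]


def sample_points(mask: np.ndarray, n_points: int,
                  seed: int | np.random.Generator,
                  max_rejection_factor: int = 10_000) -> PointSet:
    """Draw ``n_points`` uniform points over the object region of a mask.

    Points are proposed uniformly over the image rectangle; proposals on
    background are rejected and regenerated (they never count toward N).
    Each accepted point carries its xi classification. Raises
    ``DegenerateMaskError`` if total proposals exceed
    ``max_rejection_factor * n_points``.
    """
    mask = np.asarray(mask)
    if n_points < 1:
        raise ParameterError("n_points must be >= 1")
    obj = mask != BACKGROUND
    if not obj.any():
        raise EmptyDomainError("mask contains no object pixels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows, cols = mask.shape
    xs, ys = [], []
    accepted = 0
    proposed = 0
    cap = max_rejection_factor * n_points
    batch = max(n_points, 1024)
    while accepted < n_points:
        if proposed > cap:
            raise DegenerateMaskError(
                f"rejection sampling exceeded {cap} proposals "
                f"({accepted}/{n_points} accepted)")
        y = rng.uniform(0.0, rows, size=batch)
        x = rng.uniform(0.0, cols, size=batch)
        keep = obj[y.astype(np.intp), x.astype(np.intp)]
        xs.append(x[keep])
        ys.append(y[keep])
        accepted += int(keep.sum())
        proposed += batch
    x = np.concatenate(xs)[:n_points]
    y = np.concatenate(ys)[:n_points]
    labels = mask[y.astype(np.intp), x.astype(np.intp)]
    xi = np.ones(n_points, dtype=np.float64)
    xi[labels == DAMAGE] = 0.0
    xi[labels == BOUNDARY] = 0.5
    return PointSet(x, y, xi)


@dataclass(frozen=True)
class SliceEstimate:
    """Per-section Monte Carlo estimate with its precision."""

    kmd_i: float
    n_points: int
    xi_sum: float
    xi_sq_sum: float
    variance: float
    ci_halfwidth: float
    confidence_level: float
    seed: Optional[int] = None
    slice_index: Optional[int] = None


def estimate_slice(samples, confidence_level: float = DEFAULT_CONFIDENCE,
                   seed: Optional[int] = None,
                   slice_index: Optional[int] = None) -> SliceEstimate:
    """Turn a collection of point samples into a section estimate.

    ``samples`` may be a :class:`PointSet`, a sequence of
    :class:`PointSample`, or a bare array of xi values.
    """
    if isinstance(samples, PointSet):
        xi = samples.xi
    elif len(samples) and isinstance(samples[0], PointSample):
        xi = np.array([s.xi for s in samples], dtype=np.float64)
    else:
        xi = np.asarray(samples, dtype=np.float64)
    if xi.size == 0:
        raise ParameterError("estimate requires at least one sample")
    n = int(xi.size)
    xi_sum = float(xi.sum())
    xi_sq_sum = float((xi * xi).sum())
    mean = xi_sum / n
    variance = max(0.0, xi_sq_sum / n - mean * mean)
    halfwidth = normal_quantile(confidence_level) * np.sqrt(variance / n)
    return SliceEstimate(kmd_i=1.0 - mean, n_points=n, xi_sum=xi_sum,
                         xi_sq_sum=xi_sq_sum, variance=variance,
                         ci_halfwidth=float(halfwidth),
                         confidence_level=confidence_level,
                         seed=seed, slice_index=slice_index)


def estimate_mask(mask: np.ndarray, n_points: int = DEFAULT_N_POINTS,
                  confidence_level: float = DEFAULT_CONFIDENCE,
                  seed: int = 0, slice_index: Optional[int] = None,
                  max_rejection_factor: int = 10_000) -> SliceEstimate:
    """Sample and estimate one mask in a single call."""
    samples = sample_points(mask, n_points, seed,
                            max_rejection_factor=max_rejection_factor)
    return estimate_slice(samples, confidence_level, seed=seed,
                          slice_index=slice_index)


@dataclass(frozen=True)
class SpecimenEstimate:
    """Specimen-level coefficient: mean over the section estimates."""

    kmd: float
    slice_estimates: tuple[SliceEstimate, ...]
    kfmd_oracle: Optional[float] = None
    scenario: Optional[object] = None

    @property
    def ci_halfwidth(self) -> float:
        """Half-width for the specimen mean, propagated from the section
        variances: x_beta * sqrt(sum_j D_j / N_j) / J."""
        ests = self.slice_estimates
        z = normal_quantile(ests[0].confidence_level)
        var_mean = sum(e.variance / e.n_points for e in ests) / len(ests) ** 2
        return float(z * np.sqrt(var_mean))


def aggregate_specimen(slice_estimates: Sequence[SliceEstimate],
                       oracle: Optional[float] = None,
                       scenario=None) -> SpecimenEstimate:
    """Arithmetic mean of the per-section coefficients (J = 20 by default,
    but any number of sections is accepted)."""
    ests = tuple(slice_estimates)
    if not ests:
        raise ParameterError("aggregate requires at least one slice estimate")
    kmd = float(np.mean([e.kmd_i for e in ests]))
    return SpecimenEstimate(kmd=kmd, slice_estimates=ests,
                            kfmd_oracle=oracle, scenario=scenario)


def estimate_specimen(masks: Sequence[np.ndarray],
                      n_points: int = DEFAULT_N_POINTS,
                      confidence_level: float = DEFAULT_CONFIDENCE,
                      seed: int = 0, compute_oracle: bool = True,
                      scenario=None,
                      max_rejection_factor: int = 10_000) -> SpecimenEstimate:
    """Estimate a specimen from its stack of label masks.

    One independent point-sampling stream per section, seeded
    ``seed + slice_index`` for reproducibility with section-level
    independence. The oracle, when requested, is the mean of the exact
    per-section weighted area fractions.
    """
    masks = list(masks)
    if not masks:
        raise ParameterError("estimate requires at least one mask")
    ests = [estimate_mask(m, n_points, confidence_level, seed=seed + i,
                          slice_index=i, max_rejection_factor=max_rejection_factor)
            for i, m in enumerate(masks)]
    oracle = (float(np.mean([exact_damage_fraction(m) for m in masks]))
              if compute_oracle else None)
    return aggregate_specimen(ests, oracle=oracle, scenario=scenario)


class MonteCarloDamageEstimator(BaseEstimator):
    """Sklearn-style estimator of the specimen microdamage coefficient.

    ``fit`` consumes a single label mask or a sequence of masks (one per
    section, e.g. the output of :class:`~microdamage.imaging.CrackSegmenter`,
    with which it composes in a Pipeline) and exposes the estimates as
    fitted attributes.

    Parameters
    ----------
    n_points : points per section (accepted, in-object), default 3400.
    confidence_level : two-sided confidence level beta, default 0.95.
    random_state : root seed; section j uses stream random_state + j.
    compute_oracle : also record the exact pixel-area fraction.
    max_rejection_factor : proposal budget per accepted point.

    Attributes
    ----------
    kmd_ : specimen microdamage coefficient (mean over sections).
    slice_estimates_ : tuple of per-section :class:`SliceEstimate`.
    kfmd_oracle_ : exact-area coefficient, or None.
    ci_halfwidth_ : propagated half-width of the specimen mean.
    """

    def __init__(self, n_points: int = DEFAULT_N_POINTS,
                 confidence_level: float = DEFAULT_CONFIDENCE,
                 random_state: int = 0, compute_oracle: bool = True,
                 max_rejection_factor: int = 10_000):
        self.n_points = n_points
        self.confidence_level = confidence_level
        self.random_state = random_state
        self.compute_oracle = compute_oracle
        self.max_rejection_factor = max_rejection_factor

    def fit(self, X, y=None):
        masks = [X] if (isinstance(X, np.ndarray) and X.ndim == 2) else list(X)
        result = estimate_specimen(
            masks, n_points=self.n_points,
            confidence_level=self.confidence_level,
            seed=int(self.random_state or 0),
            compute_oracle=self.compute_oracle,
            max_rejection_factor=self.max_rejection_factor)
        self.specimen_estimate_ = result
        self.slice_estimates_ = result.slice_estimates
        self.kmd_ = result.kmd
        self.kfmd_oracle_ = result.kfmd_oracle
        self.ci_halfwidth_ = result.ci_halfwidth
        self.n_slices_ = len(result.slice_estimates)
        return self

    def score(self, X=None, y=None):
        """Negative specimen CI half-width (tighter is better)."""
        return -self.ci_halfwidth_


# ---------------------------------------------------------------------------
# result serialization

def write_slice_estimates_csv(estimates: Sequence[SliceEstimate], path) -> None:
    import pandas as pd

    rows = [{"slice_index": e.slice_index, "n_points": e.n_points,
             "kmd_i": e.kmd_i, "variance": e.variance,
             "ci_halfwidth": e.ci_halfwidth} for e in estimates]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_specimen_json(est: SpecimenEstimate, path, seed: Optional[int] = None) -> None:
    payload = {
        "kmd": est.kmd,
        "kfmd_oracle": est.kfmd_oracle,
        "ci_halfwidth": est.ci_halfwidth,
        "n_sections": len(est.slice_estimates),
        "n_points": est.slice_estimates[0].n_points,
        "confidence_level": est.slice_estimates[0].confidence_level,
        "seed": seed,
    }
    if est.scenario is not None:
        sc = est.scenario
        payload["scenario"] = {
            "load_type": getattr(sc, "load_type", None),
            "orientation": getattr(sc, "orientation", None),
            "load_fraction": getattr(sc, "load_fraction", None),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
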