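"""Probabilistic LC-space boundary estimation.

Labelled segments are points in the (mutation %, dominance %) plane: the
positive class is low-complexity, the negative class a disorder-grounded
background.  Two estimators of P(LC | x, y) are provided:

1. a **binned** estimator — the plane is discretised into Delta-wide bins
   (default 2%) and each bin's probability is the smoothed frequency ratio

       P(LC | i, j) = (n+ + a) / (n+ + n- + 2a),       a = 1,

   which stays strictly inside (0,1) even for empty bins;
2. a **smooth** estimator — a tensor-product B-spline logistic model
   logit p(x, y) = f(x, y) with an L2 roughness penalty chosen by
   cross-validation, a smooth-surface analog (not a replica) of a penalised
   regression-spline GAM.

Either surface scores held-out points; ROC analysis with the P >= t decision
rule and Youden's J = TPR - FPR selects the operating threshold t*, and the
LC boundary is the contour where the surface equals t*.  The boundary is a
confidence envelope, not a sharp delimiter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure
from sklearn.linear_model import LogisticRegressionCV
from sklearn.preprocessing import SplineTransformer

__all__ = [
    "LabeledPoint",
    "BinnedSurface",
    "RocCurve",
    "SmoothSurface",
    "bin_points",
    "posterior_probability",
    "score_points",
    "roc_curve",
    "youden_optimal",
    "boundary_contour",
    "fit_smooth_surface",
    "split_points",
    "lc_permissive_fraction",
]

POSITIVE, NEGATIVE = "LC", "BG"


@dataclass(frozen=True)
class LabeledPoint:
    """A segment's LC-space coordinates with its class label."""

    x: float
    y: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}, got {self.label!r}")


@dataclass
class BinnedSurface:
    """Discretised LC space with smoothed per-bin class probabilities."""

    delta: float
    pseudocount: float
    n_pos: np.ndarray  # shape (nbins, nbins), indexed [ix, iy]
    n_neg: np.ndarray

    @property
    def nbins(self) -> int:
        return self.n_pos.shape[0]

    @property
    def prob(self) -> np.ndarray:
        a = self.pseudocount
        with np.errstate(invalid="ignore"):
            # a = 0 leaves empty bins undefined (NaN): the unsmoothed
            # empirical frequency simply does not exist there
            return (self.n_pos + a) / (self.n_pos + self.n_neg + 2 * a)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.nbins) + 0.5) * self.delta


@dataclass
class RocCurve:
    """Threshold sweep of the P >= t decision rule."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    @property
    def youden_j(self) -> np.ndarray:
        return self.tpr - self.fpr


def _bin_index(values: np.ndarray, delta: float, nbins: int) -> np.ndarray:
    idx = np.floor(values / delta).astype(int)
    # the top edge (coordinate exactly 100) is closed into the last bin
    return np.minimum(idx, nbins - 1)


def bin_points(
    points: Sequence[LabeledPoint], delta: float = 2.0, pseudocount: float = 1.0
) -> BinnedSurface:
    """Count points into half-open Delta-wide bins [k*Delta, (k+1)*Delta).

    ``delta`` must divide 100 evenly; out-of-range points are an error.
    """
    nbins = round(100.0 / delta)
    if abs(nbins * delta - 100.0) > 1e-9:
        raise ValueError(f"delta={delta} does not divide 100 evenly")
    xs = np.array([p.x for p in points], dtype=float)
    ys = np.array([p.y for p in points], dtype=float)
    bad = [
        p for p in points if not (0.0 <= p.x <= 100.0 and 0.0 <= p.y <= 100.0)
    ]
    if bad:
        raise ValueError(f"points outside [0,100]^2: {bad[:5]}" + ("..." if len(bad) > 5 else ""))
    n_pos = np.zeros((nbins, nbins))
    n_neg = np.zeros((nbins, nbins))
    if len(points):
        ix = _bin_index(xs, delta, nbins)
        iy = _bin_index(ys, delta, nbins)
        pos = np.array([p.label == POSITIVE for p in points])
        np.add.at(n_pos, (ix[pos], iy[pos]), 1)
        np.add.at(n_neg, (ix[~pos], iy[~pos]), 1)
    return BinnedSurface(delta=delta, pseudocount=pseudocount, n_pos=n_pos, n_neg=n_neg)


def posterior_probability(surface: BinnedSurface) -> np.ndarray:
    """Per-bin smoothed frequency-ratio probabilities (see module docstring)."""
    return surface.prob


def score_points(surface: "BinnedSurface | SmoothSurface", points: Sequence[LabeledPoint]) -> np.ndarray:
    """Probability assigned by a surface to each point."""
    xs = np.array([p.x for p in points], dtype=float)
    ys = np.array([p.y for p in points], dtype=float)
    if isinstance(surface, BinnedSurface):
        prob = surface.prob
        ix = _bin_index(xs, surface.delta, surface.nbins)
        iy = _bin_index(ys, surface.delta, surface.nbins)
        return prob[ix, iy]
    return surface.predict(xs, ys)


def roc_curve(
    scores: np.ndarray, labels: Sequence[str], thresholds: np.ndarray | None = None
) -> RocCurve:
    """TPR/FPR at each threshold of the P >= t rule.

    Thresholds default to the sorted unique scores plus {0, 1}.  Requires at
    least one point of each class.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.array([l == POSITIVE for l in labels])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis requires both classes among the evaluated points")
    if thresholds is None:
        thresholds = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    thresholds = np.asarray(thresholds, dtype=float)
    calls = scores[None, :] >= thresholds[:, None]
    tpr = (calls & pos).sum(axis=1) / n_pos
    fpr = (calls & ~pos).sum(axis=1) / n_neg
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr)


def youden_optimal(roc: RocCurve) -> float:
    """Threshold maximising J = TPR - FPR; ties broken by the smallest t."""
    j = roc.youden_j
    return float(roc.thresholds[int(np.argmax(j))])


def boundary_contour(
    surface: "BinnedSurface | SmoothSurface", t_star: float
) -> list[np.ndarray]:
    """Level set P = t* as polylines of (x, y) coordinates in percent.

    Marching squares on the evaluation grid with linear interpolation; may be
    empty (surface entirely above or below t*) or contain several open/closed
    polylines.
    """
    if isinstance(surface, BinnedSurface):
        grid, centers = surface.prob, surface.centers
    else:
        grid, centers = surface.grid_prob, surface.grid_centers
    step = centers[1] - centers[0] if len(centers) > 1 else 1.0
    contours = measure.find_contours(grid, t_star)
    # find_contours returns (row, col) = (ix, iy) fractional indices
    return [centers[0] + c * step for c in contours]


@dataclass
class SmoothSurface:
    """A fitted smooth logistic surface over LC space."""

    model: object
    transform_x: SplineTransformer
    transform_y: SplineTransformer
    grid_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    grid_prob: np.ndarray = field(default_factory=lambda: np.array([[]]))

    def _features(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        bx = self.transform_x.transform(xs.reshape(-1, 1))
        by = self.transform_y.transform(ys.reshape(-1, 1))
        return np.einsum("ni,nj->nij", bx, by).reshape(len(xs), -1)

    def predict(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Probabilities, strictly inside (0, 1)."""
        p = self.model.predict_proba(self._features(np.asarray(xs, float), np.asarray(ys, float)))[:, 1]
        eps = np.finfo(float).tiny
        return np.clip(p, eps, 1 - eps)


def fit_smooth_surface(
    points: Sequence[LabeledPoint],
    n_knots: int = 8,
    degree: int = 3,
    grid_step: float = 2.0,
    seed: int = 0,
    min_points: int = 100,
) -> SmoothSurface:
    """Fit the tensor-product spline logistic surface.

    Cubic B-spline bases on each axis (``n_knots`` uniform knots over
    [0, 100]) are combined into a tensor-product design; an L2 penalty on the
    coefficients controls roughness and its strength is chosen by 5-fold
    cross-validation.  The fitted surface is evaluated on a regular grid of
    bin centers (``grid_step`` percent) for contour extraction.
    """
    if len(points) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(points)}")
    labels = np.array([p.label == POSITIVE for p in points], dtype=int)
    if labels.min() == labels.max():
        raise ValueError("smooth-surface fit requires both classes")
    xs = np.array([p.x for p in points], dtype=float)
    ys = np.array([p.y for p in points], dtype=float)
    tx = SplineTransformer(
        n_knots=n_knots, degree=degree, knots=np.linspace(0, 100, n_knots).reshape(-1, 1)
    ).fit(xs.reshape(-1, 1))
    ty = SplineTransformer(
        n_knots=n_knots, degree=degree, knots=np.linspace(0, 100, n_knots).reshape(-1, 1)
    ).fit(ys.reshape(-1, 1))
    surface = SmoothSurface(model=None, transform_x=tx, transform_y=ty)
    feats = surface._features(xs, ys)
    model = LogisticRegressionCV(
        Cs=np.logspace(-3, 3, 7), cv=5, max_iter=5000,
        random_state=seed, scoring="neg_log_loss",
    )
    model.fit(feats, labels)
    surface.model = model
    centers = (np.arange(round(100.0 / grid_step)) + 0.5) * grid_step
    gx, gy = np.meshgrid(centers, centers, indexing="ij")
    surface.grid_centers = centers
    surface.grid_prob = surface.predict(gx.ravel(), gy.ravel()).reshape(gx.shape)
    return surface


def split_points(
    points: Sequence[LabeledPoint], frac_train: float = 0.5, seed: int = 0
) -> tuple[list[LabeledPoint], list[LabeledPoint]]:
    """Stratified train/held-out split (default 50/50), deterministic per seed."""
    rng = np.random.default_rng(seed)
    train: list[LabeledPoint] = []
    heldout: list[LabeledPoint] = []
    for label in (POSITIVE, NEGATIVE):
        group = [p for p in points if p.label == label]
        order = rng.permutation(len(group))
        n_train = int(round(frac_train * len(group)))
        for rank, idx in enumerate(order):
            (train if rank < n_train else heldout).append(group[idx])
    return train, heldout


def lc_permissive_fraction(surface: "BinnedSurface | SmoothSurface", t_star: float) -> float:
    """Fraction of the evaluation grid classified LC (P >= t*)."""
    grid = surface.prob if isinstance(surface, BinnedSurface) else surface.grid_prob
    return float(np.mean(grid >= t_star))
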