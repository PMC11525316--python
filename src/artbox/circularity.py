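"""Quantifying the circularity of a perceptual space from similarity judgments.

Pipeline: trial-level Likert similarity ratings (0 = no similarity,
5 = identical) between tone pairs are screened for inattentive participants,
averaged into per-participant similarity matrices, pooled and reverse-coded
into a group dissimilarity matrix, embedded in two dimensions with metric
SMACOF multidimensional scaling, affine-aligned across participant sets on
shared anchor tones, closed with a periodic cubic spline, and finally scored
with the isoperimetric circularity quotient

    C = 4 * pi * Area / Perimeter**2

which is 1 for a perfect circle and smaller for any other closed shape
(pi/4 for a square; (pi/n) * cot(pi/n) for a regular n-gon).  A value of
0.9 or higher is treated as nearly perfect circularity.

Trial tables are pandas DataFrames with columns ``participant_id``,
``tone_a``, ``tone_b``, ``rating`` (see :mod:`artbox.simulate` for the
generator that emits them).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.manifold import smacof

__all__ = [
    "LIKERT_MAX",
    "SimilarityMatrix",
    "DissimilarityMatrix",
    "PerceptualConfiguration",
    "ClosedCurve",
    "exclude_participants",
    "aggregate_similarity",
    "group_dissimilarity",
    "mds_embed",
    "affine_align",
    "combine_configurations",
    "periodic_spline",
    "polygon_area",
    "polygon_perimeter",
    "circularity",
    "regular_polygon_circularity",
    "circularity_report",
]

LIKERT_MAX = 5  # top of the similarity scale; reverse coding subtracts from it


@dataclass(frozen=True)
class SimilarityMatrix:
    labels: np.ndarray  # tone degrees, ascending
    values: np.ndarray  # n x n mean ratings, symmetric


@dataclass(frozen=True)
class DissimilarityMatrix:
    labels: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class PerceptualConfiguration:
    labels: np.ndarray
    points: np.ndarray  # (n, 2)
    stress: float = 0.0


@dataclass(frozen=True)
class ClosedCurve:
    samples: np.ndarray = field(repr=False)  # (m, 2), first == last
    area: float = 0.0
    perimeter: float = 0.0
    C: float = 0.0


# ---------------------------------------------------------------------------
# participant screening and matrix construction
# ---------------------------------------------------------------------------

def exclude_participants(trials: pd.DataFrame, threshold: float = 4.0) -> list:
    """Participants retained by the self-similarity criterion.

    A participant is kept only if their mean rating on identical-pair trials
    (tone_a == tone_b) reaches ``threshold`` (default 4 on the 0-5 scale);
    lower means indicate an inability to discriminate the tones at all.
    """
    retained = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        self_trials = sub[sub["tone_a"] == sub["tone_b"]]
        if self_trials.empty:
            raise ValueError(f"participant {pid!r} has no identical-pair trials")
        if self_trials["rating"].mean() >= threshold:
            retained.append(pid)
    return retained


def aggregate_similarity(trials: pd.DataFrame, participant) -> SimilarityMatrix:
    """Per-participant mean similarity matrix, symmetrized over pair order."""
    sub = trials[trials["participant_id"] == participant]
    if sub.empty:
        raise ValueError(f"no trials for participant {participant!r}")
    labels = np.unique(np.concatenate([sub["tone_a"].values, sub["tone_b"].values]))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for a, b, r in zip(sub["tone_a"], sub["tone_b"], sub["rating"]):
        i, j = index[a], index[b]
        total[i, j] += r
        count[i, j] += 1
        if i != j:
            total[j, i] += r
            count[j, i] += 1
    missing = np.argwhere(count == 0)
    if missing.size:
        i, j = missing[0]
        raise ValueError(
            f"participant {participant!r}: no rating for pair "
            f"({labels[i]}, {labels[j]})"
        )
    return SimilarityMatrix(labels=labels, values=total / count)


def group_dissimilarity(matrices: list[SimilarityMatrix]) -> DissimilarityMatrix:
    """Reverse-coded group matrix: ``LIKERT_MAX -`` mean participant similarity."""
    if not matrices:
        raise ValueError("need at least one similarity matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if not np.array_equal(m.labels, labels):
            raise ValueError("similarity matrices have mismatched labels")
    mean_sim = np.mean([m.values for m in matrices], axis=0)
    return DissimilarityMatrix(labels=labels.copy(), values=LIKERT_MAX - mean_sim)


# ---------------------------------------------------------------------------
# embedding and alignment
# ---------------------------------------------------------------------------

def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centering start for SMACOF."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


def mds_embed(
    dissim: DissimilarityMatrix,
    dims: int = 2,
    max_iter: int = 300,
    eps: float = 1e-9,
) -> PerceptualConfiguration:
    """Metric SMACOF embedding of a dissimilarity matrix.

    Deterministic: initialized from the classical (Torgerson) solution and
    run as a single majorization pass with a fixed iteration cap.  The
    returned stress is raw metric stress (sum of squared residual
    distances).
    """
    d = np.asarray(dissim.values, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if d.shape[0] < 4:
        raise ValueError("need at least four items to embed")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    work = d.copy()
    np.fill_diagonal(work, 0.0)
    init = _classical_mds(work, dims)
    points, stress = smacof(
        work,
        metric=True,
        n_components=dims,
        init=init,
        n_init=1,
        max_iter=max_iter,
        eps=eps,
        normalized_stress=False,
    )
    return PerceptualConfiguration(
        labels=dissim.labels.copy(), points=points, stress=float(stress)
    )


def _anchor_points(cfg: PerceptualConfiguration, anchor_labels) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(cfg.labels)}
    try:
        rows = [index[a] for a in anchor_labels]
    except KeyError as err:
        raise ValueError(f"anchor label {err.args[0]!r} not in configuration") from err
    return cfg.points[rows]


def affine_align(
    source: PerceptualConfiguration,
    reference: PerceptualConfiguration,
    anchor_labels,
) -> PerceptualConfiguration:
    """Map ``source`` onto ``reference`` by a least-squares 2-D affine fit.

    The six affine parameters are fitted on the anchor points shared by both
    configurations and then applied to every source point.  With exactly
    three non-collinear anchors the map interpolates them exactly.
    """
    anchors = list(anchor_labels)
    if len(anchors) < 3:
        raise ValueError("need at least three anchor labels")
    src = _anchor_points(source, anchors)
    ref = _anchor_points(reference, anchors)
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("anchor points are collinear; affine map is degenerate")
    coef, *_ = np.linalg.lstsq(design, ref, rcond=None)
    mapped = np.column_stack([source.points, np.ones(len(source.points))]) @ coef
    return PerceptualConfiguration(
        labels=source.labels.copy(), points=mapped, stress=source.stress
    )


def combine_configurations(
    cfg1: PerceptualConfiguration,
    cfg2_aligned: PerceptualConfiguration,
    anchor_labels,
) -> PerceptualConfiguration:
    """Union of two aligned configurations, averaging each shared anchor."""
    anchors = set(anchor_labels)
    pts: dict = {lab: p for lab, p in zip(cfg1.labels, cfg1.points)}
    for lab, p in zip(cfg2_aligned.labels, cfg2_aligned.points):
        if lab in pts:
            if lab not in anchors:
                raise ValueError(f"non-anchor label {lab!r} present in both sets")
            pts[lab] = 0.5 * (pts[lab] + p)
        else:
            pts[lab] = p
    labels = np.array(sorted(pts))
    points = np.vstack([pts[lab] for lab in labels])
    return PerceptualConfiguration(
        labels=labels,
        points=points,
        stress=0.5 * (cfg1.stress + cfg2_aligned.stress),
    )


# ---------------------------------------------------------------------------
# curve closure and the circularity quotient
# ---------------------------------------------------------------------------

def periodic_spline(config: PerceptualConfiguration, samples: int = 1000) -> ClosedCurve:
    """Close the configuration with a periodic cubic spline.

    Points are ordered by tone degree and parameterized by that degree, with
    the first point repeated one full turn later so the spline wraps with
    continuous first and second derivatives.  The densely sampled curve
    passes through every input point.
    """
    if len(config.labels) < 4:
        raise ValueError("need at least four points for a periodic spline")
    order = np.argsort(config.labels)
    degs = np.asarray(config.labels, dtype=float)[order]
    if np.unique(degs).size != degs.size:
        raise ValueError("duplicate tone degrees; ordering is ambiguous")
    pts = config.points[order]
    t = np.concatenate([degs, [degs[0] + 360.0]])
    closed = np.vstack([pts, pts[:1]])
    spline = CubicSpline(t, closed, axis=0, bc_type="periodic")
    dense_t = np.linspace(t[0], t[-1], samples + 1)
    dense = spline(dense_t)
    area = polygon_area(dense, closed_path=True)
    perim = polygon_perimeter(dense, closed_path=True)
    return ClosedCurve(
        samples=dense,
        area=area,
        perimeter=perim,
        C=4.0 * math.pi * area / perim**2,
    )


def _close(points: np.ndarray, closed_path: bool) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if not closed_path:
        pts = np.vstack([pts, pts[:1]])
    return pts


def polygon_area(points: np.ndarray, closed_path: bool = False) -> float:
    """Unsigned shoelace area of a closed path (auto-closing if needed)."""
    pts = _close(points, closed_path)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])))


def polygon_perimeter(points: np.ndarray, closed_path: bool = False) -> float:
    pts = _close(points, closed_path)
    return float(np.sum(np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))))


def _is_simple(points: np.ndarray) -> bool:
    """Check a closed polyline for self-intersection (shapely)."""
    try:
        from shapely.geometry import LinearRing

        return LinearRing(points[:-1]).is_valid
    except Exception:
        return True  # fall back to trusting the path


def circularity(shape, closed_path: bool = False) -> float:
    """Isoperimetric quotient ``C = 4 * pi * Area / Perimeter**2``.

    ``shape`` is a :class:`ClosedCurve` or an (n, 2) vertex array (closed
    automatically unless ``closed_path``).  C is invariant to rotation,
    translation, reflection and uniform scaling; it is 1 for a circle and
    strictly below 1 for everything else.  A self-intersecting path draws a
    warning and is scored on the absolute shoelace area.
    """
    if isinstance(shape, ClosedCurve):
        return shape.C
    pts = _close(shape, closed_path)
    if len(pts) < 4:  # 3 vertices + closure
        raise ValueError("need at least three points")
    area = polygon_area(pts, closed_path=True)
    perim = polygon_perimeter(pts, closed_path=True)
    if not _is_simple(pts):
        warnings.warn("self-intersecting path; using absolute shoelace area")
    if area <= 0 or perim <= 0:
        raise ValueError("degenerate shape: zero area or perimeter")
    return 4.0 * math.pi * area / perim**2


def regular_polygon_circularity(n: int) -> float:
    """Closed form ``(pi / n) * cot(pi / n)`` for the regular n-gon."""
    if n < 3:
        raise ValueError("a polygon needs at least three sides")
    return (math.pi / n) / math.tan(math.pi / n)


# ---------------------------------------------------------------------------
# end-to-end report
# ---------------------------------------------------------------------------

def circularity_report(
    trials: pd.DataFrame,
    tone_sets: dict,
    anchors,
    spline_samples: int = 1000,
) -> dict:
    """Run the full circularity analysis on a trial table.

    ``tone_sets`` maps a set name to the list of participant ids whose
    ratings form that set (each set shares one tone inventory); with two
    sets the second embedding is affine-aligned to the first on the anchor
    tones and the configurations are merged.  Returns the splined and
    polygonal circularity quotients, the combined configuration and
    book-keeping about exclusions.
    """
    retained = set(exclude_participants(trials))
    all_ids = set(trials["participant_id"].unique())
    excluded = sorted(all_ids - retained)

    configs = []
    for name, pids in tone_sets.items():
        kept = [p for p in pids if p in retained]
        if not kept:
            raise ValueError(f"tone set {name!r} has no retained participants")
        mats = [aggregate_similarity(trials, p) for p in kept]
        configs.append(mds_embed(group_dissimilarity(mats)))

    if len(configs) == 1:
        combined = configs[0]
    elif len(configs) == 2:
        aligned = affine_align(configs[1], configs[0], anchors)
        combined = combine_configurations(configs[0], aligned, anchors)
    else:
        raise ValueError("circularity_report supports one or two tone sets")

    curve = periodic_spline(combined, samples=spline_samples)
    order = np.argsort(combined.labels)
    c_polygon = circularity(combined.points[order])
    return {
        "C_spline": curve.C,
        "C_polygon": c_polygon,
        "stress": combined.stress,
        "configuration": combined,
        "curve": curve,
        "n_retained": len(retained),
        "excluded_ids": excluded,
    }
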