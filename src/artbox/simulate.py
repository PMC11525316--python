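"""Synthetic datasets with the statistical structure the analyses assume.

Two generators:

* :func:`gen_similarity_study` emulates a two-set similarity-rating study on
  the discrete Shepard tone inventory: every unordered tone pair is rated
  eight times per participant (self-pairs twice), and the mean rating falls
  off linearly with circular angular distance between the tones.  The
  default intercept/slope are the least-squares line through the observed
  group means 3.98 at 24 deg and 1.92 at 192 deg, so the generator's
  noise-free mean at 24 deg reproduces 3.98 by construction.
* :func:`gen_reproduction_study` emulates a delayed-estimation experiment on
  the full 1-360 deg space: uniform targets, block structure, a probed
  serial position chosen at random, and signed errors drawn from the
  standard mixture (set size 1) or swap model (set size 2+).

Both are deterministic given their seed and emit the trial-table dialects
consumed by :mod:`artbox.circularity` and :mod:`artbox.mixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture import sd_to_kappa, wrap

__all__ = [
    "TONE_SET_1",
    "TONE_SET_2",
    "ANCHORS",
    "SimilarityGenSpec",
    "ReproductionGenSpec",
    "circular_distance",
    "gen_similarity_study",
    "gen_reproduction_study",
]

# Discrete tone inventories (degrees on the circular space) of the two
# participant sets; three anchors 120 deg apart are shared between sets.
TONE_SET_1 = (48, 96, 120, 168, 216, 240, 288, 336, 360)
TONE_SET_2 = (24, 72, 120, 144, 192, 240, 264, 312, 360)
ANCHORS = (120, 240, 360)


def circular_distance(a, b):
    """Shortest angular distance on the circle, degrees in [0, 180]."""
    return np.abs(wrap(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


@dataclass(frozen=True)
class SimilarityGenSpec:
    """Parameters of the synthetic similarity-rating study.

    ``intercept`` and ``slope`` define the mean Likert rating as
    ``intercept - slope * circular_distance`` before noise and rounding;
    ``n_bad_per_set`` plants extra participants whose self-similarity
    ratings are low, for exercising the exclusion rule.
    """

    tone_sets: tuple = (TONE_SET_1, TONE_SET_2)
    anchors: tuple = ANCHORS
    n_participants_per_set: int = 12
    n_bad_per_set: int = 0
    intercept: float = 4.274
    slope: float = 0.01226
    noise_sd: float = 0.7
    repeats_per_pair: int = 8
    self_repeats: int = 2
    discretize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intercept > 5 or self.noise_sd < 0:
            raise ValueError("invalid similarity generator parameters")
        if self.intercept - 180.0 * self.slope < 0:
            raise ValueError("mean rating would go negative at 180 deg distance")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def gen_similarity_study(spec: SimilarityGenSpec = SimilarityGenSpec()) -> pd.DataFrame:
    """Trial table of a full synthetic similarity-rating study.

    Columns: participant_id, set (1-based), tone_a, tone_b, rating, order.
    Ratings are ``round(clip(intercept - slope * dist + N(0, noise), 0, 5))``
    for distinct pairs; self-pairs draw from N(4.8, 0.3) for good
    participants and N(3.0, 0.4) for planted bad ones.  With
    ``discretize=False`` the clipped real-valued ratings are kept — integer
    Likert rounding quantizes a noise-free study into a handful of distance
    levels, which distorts the downstream embedding.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    pid = 0
    for set_idx, tones in enumerate(spec.tone_sets, start=1):
        tones = tuple(tones)
        n_total = spec.n_participants_per_set + spec.n_bad_per_set
        for p in range(n_total):
            pid += 1
            bad = p >= spec.n_participants_per_set
            order = 0
            for i, a in enumerate(tones):
                for b in tones[i:]:
                    if a == b:
                        loc, scale = (3.0, 0.4) if bad else (4.8, 0.3)
                        raw = rng.normal(loc, scale, size=spec.self_repeats)
                    else:
                        mean = spec.intercept - spec.slope * float(
                            circular_distance(a, b)
                        )
                        raw = mean + rng.normal(0.0, spec.noise_sd, size=spec.repeats_per_pair)
                    clipped = np.clip(raw, 0.0, 5.0)
                    if spec.discretize:
                        clipped = _round_half_up(clipped)
                    for r in clipped:
                        order += 1
                        rows.append(
                            {
                                "participant_id": f"s{set_idx}p{p + 1:02d}",
                                "set": set_idx,
                                "tone_a": a,
                                "tone_b": b,
                                "rating": int(r) if spec.discretize else float(r),
                                "order": order,
                            }
                        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReproductionGenSpec:
    """Parameters of the synthetic delayed-estimation study.

    ``params`` maps set size to mixture parameters ``(g, beta, sd)``; the
    defaults are the observed set-size-1 standard-model estimates
    (g = 0.18, sd = 29.1 deg) and the set-size-2 swap decomposition
    (g = 0.18, beta = 0.11, sd = 30.65 deg).  The default design is
    4 blocks of 50 trials split evenly between set sizes.
    """

    set_sizes: tuple = (1, 2)
    params: dict = field(
        default_factory=lambda: {
            1: (0.18, 0.0, 29.1),
            2: (0.18, 0.11, 30.65),
        }
    )
    n_participants: int = 18
    blocks: int = 4
    trials_per_block: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for ss in self.set_sizes:
            g, beta, sd = self.params[ss]
            if not (0 <= g and 0 <= beta and g + beta <= 1) or sd <= 0:
                raise ValueError(f"invalid mixture parameters for set size {ss}")
            if beta > 0 and ss < 2:
                raise ValueError("swap errors require at least two items")
            sd_to_kappa(sd)  # validates range


def gen_reproduction_study(
    spec: ReproductionGenSpec = ReproductionGenSpec(),
) -> pd.DataFrame:
    """Trial table of a full synthetic reproduction study.

    Columns: participant_id, block, set_size, serial_position, target_deg,
    response_deg, nontarget_deg (NaN for set size 1).  Targets and
    non-targets are uniform on (0, 360]; the probed serial position is
    uniform over the items; the signed error is drawn from the mixture for
    that set size (guess -> uniform response, swap -> centred on the
    non-target, otherwise centred on the target).
    """
    rng = np.random.default_rng(spec.seed)
    n_ss = len(spec.set_sizes)
    if spec.trials_per_block % n_ss:
        raise ValueError("trials_per_block must divide evenly between set sizes")
    per_ss = spec.trials_per_block // n_ss
    rows = []
    for p in range(1, spec.n_participants + 1):
        for block in range(1, spec.blocks + 1):
            cond = np.repeat(spec.set_sizes, per_ss)
            rng.shuffle(cond)
            for ss in cond:
                g, beta, sd = spec.params[ss]
                kappa = sd_to_kappa(sd)
                items = rng.uniform(0.0, 360.0, size=ss)
                probe_idx = int(rng.integers(0, ss))
                target = items[probe_idx]
                others = np.delete(items, probe_idx)
                u = rng.random()
                noise = float(np.degrees(rng.vonmises(0.0, kappa)))
                if u < g:
                    response = rng.uniform(0.0, 360.0)
                elif u < g + beta and others.size:
                    centre = others[int(rng.integers(0, others.size))]
                    response = centre + noise
                else:
                    response = target + noise
                response = float(np.mod(response, 360.0))
                rows.append(
                    {
                        "participant_id": f"p{p:02d}",
                        "block": block,
                        "set_size": int(ss),
                        "serial_position": probe_idx + 1,
                        "target_deg": float(target),
                        "response_deg": response,
                        "nontarget_deg": float(others[0]) if others.size else np.nan,
                    }
                )
    return pd.DataFrame(rows)
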