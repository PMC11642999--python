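"""Open-set recognition core: mean activation vectors, Weibull distance
tails, score recalibration, and the OpenMax rejection procedure.

The model of "known" behaviour is deliberately simple. For each known class
c we store the Mean Activation Vector (MAV) — the arithmetic mean of the
class's training activation vectors — and a Weibull model of the *tail* of
the Euclidean distances between those training activations and the MAV.
Extreme-value theory motivates the Weibull: the largest within-class
distances characterize how far a genuine member of the class can plausibly
sit from its centre, so the fitted CDF turns a test sample's distance into
"how extreme would this be for a true member?".

Two rejection procedures are provided:

* ``score_threshold`` — per class, the recalibrated score
  ``r_c = 1 - CDF_c(||z - MAV_c||)`` is near 1 for typical members and near
  0 for outliers; a sample is rejected as unknown when ``max_c r_c`` falls
  below a threshold, otherwise the argmax class wins.
* ``openmax`` — the activation vector itself is down-weighted class by
  class (the β top-ranked classes get factor
  ``θ = 1 - ((β-j)/β) * CDF``), the mass removed is routed to a synthetic
  unknown class, and a softmax over the M+1 augmented activations yields
  probabilities; the sample is rejected when the unknown class wins or the
  winning probability is below the threshold.

All tie-breaks take the lowest vocabulary index; the vocabulary is the
sorted order of the training labels unless given explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DegenerateTailError,
    InvalidArgumentError,
    ModelBuildError,
)
from .types import UNKNOWN_LABEL, ActivationRecord, ActivationSet

DECISION_MODES = ("score_threshold", "openmax")
MAV_SOURCES = ("all_samples", "correct_only")
LOCATION_MODES = ("zero", "tail_min")


# ---------------------------------------------------------------------------
# Weibull tail
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeibullTail:
    """Three-parameter Weibull CDF over distances: shape, scale, location."""

    shape: float
    scale: float
    location: float = 0.0

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0 and self.location >= 0):
            raise InvalidArgumentError(
                f"invalid Weibull parameters shape={self.shape}, "
                f"scale={self.scale}, location={self.location}"
            )

    def cdf(self, distance):
        return weibull_cdf(distance, self)


def weibull_cdf(distance, tail: WeibullTail):
    """``1 - exp(-((d - location)/scale)^shape)`` for d above the location, else 0."""
    d = np.asarray(distance, dtype=float)
    x = np.maximum(d - tail.location, 0.0) / tail.scale
    out = -np.expm1(-np.power(x, tail.shape))
    return float(out) if np.isscalar(distance) or d.ndim == 0 else out


def _profile_score(k: float, lx: np.ndarray, u: np.ndarray):
    """Profile log-likelihood score g(k) and its derivative for Weibull MLE.

    With scale profiled out, the stationarity condition in the shape k is
    ``g(k) = 1/k + mean(log x) - sum(x^k log x)/sum(x^k) = 0``; ``u`` holds
    the data scaled by its maximum so powers never overflow.
    """
    uk = np.power(u, k)
    b = uk.sum()
    a = (uk * lx).sum()
    a2 = (uk * lx * lx).sum()
    g = 1.0 / k + lx.mean() - a / b
    gprime = -1.0 / (k * k) - (a2 * b - a * a) / (b * b)
    return g, gprime


def fit_weibull_tail(
    distances: Sequence[float] | np.ndarray,
    tail_size: int,
    location_mode: str = "tail_min",
) -> WeibullTail:
    """Fit a Weibull to the ``tail_size`` largest distances by maximum likelihood.

    The location is fixed first — ``zero`` leaves distances untranslated,
    ``tail_min`` (the default, and the meta-recognition convention) subtracts
    ``(1 - 1e-6) * min(tail)`` so the fit models exceedances over the tail's
    onset. Shape and scale are then estimated by safeguarded Newton iteration
    on the profile likelihood (tolerance 1e-10, at most 200 iterations), with
    bisection as the fallback when a Newton step leaves the bracket.
    """
    if tail_size < 2:
        raise InvalidArgumentError(f"tail_size must be >= 2, got {tail_size}")
    if location_mode not in LOCATION_MODES:
        raise InvalidArgumentError(
            f"location_mode must be one of {LOCATION_MODES}, got {location_mode!r}"
        )
    d = np.sort(np.asarray(distances, dtype=float))
    if d.size < tail_size:
        raise InvalidArgumentError(
            f"need at least tail_size={tail_size} distances, got {d.size}"
        )
    tail = d[-tail_size:]
    if tail[0] == tail[-1]:
        raise DegenerateTailError("all tail distances are equal; nothing to fit")
    location = 0.0 if location_mode == "zero" else (1.0 - 1e-6) * float(tail[0])
    x = tail - location
    if x[0] <= 0.0:
        raise DegenerateTailError("tail contains non-positive distances after translation")

    lx = np.log(x)
    u = x / x[-1]
    # Moment start: Var(log X) = pi^2 / (6 k^2) for a Weibull.
    sd = lx.std()
    k = float(np.clip((np.pi / np.sqrt(6.0)) / sd if sd > 0 else 1.0, 1e-3, 1e3))

    # g(k) is strictly decreasing; bracket a sign change, then Newton+bisect.
    lo, hi = 1e-8, k
    while _profile_score(hi, lx, u)[0] > 0 and hi < 1e12:
        lo, hi = hi, hi * 2.0
    for _ in range(200):
        g, gp = _profile_score(k, lx, u)
        if g > 0:
            lo = k
        else:
            hi = k
        step = g / gp if gp != 0 else 0.0
        k_new = k - step
        if not (lo < k_new < hi):
            k_new = 0.5 * (lo + hi)
        if abs(k_new - k) <= 1e-10 * max(1.0, abs(k)):
            k = k_new
            break
        k = k_new
    scale = float(x[-1] * np.power(np.mean(np.power(u, k)), 1.0 / k))
    return WeibullTail(shape=float(k), scale=scale, location=location)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpenMaxConfig:
    """Knobs of the open-set procedure.

    ``beta`` is the number of top-ranked classes whose activations are
    down-weighted (``None`` means all M classes). ``tail_size`` caps the
    per-class tail at ``min(tail_size, N_c)``. ``threshold`` is the
    rejection cutoff ε applied to the max recalibrated score
    (``score_threshold`` mode) or to the winning OpenMax probability
    (``openmax`` mode).
    """

    beta: int | None = None
    tail_size: int = 20
    threshold: float = 0.1
    decision_mode: str = "score_threshold"
    mav_source: str = "all_samples"
    location_mode: str = "tail_min"
    unknown_label: str = UNKNOWN_LABEL

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta < 0:
            raise ConfigError(f"beta must be >= 0, got {self.beta}")
        if self.tail_size < 2:
            raise ConfigError(f"tail_size must be >= 2, got {self.tail_size}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.decision_mode not in DECISION_MODES:
            raise ConfigError(
                f"decision_mode must be one of {DECISION_MODES}, got {self.decision_mode!r}"
            )
        if self.mav_source not in MAV_SOURCES:
            raise ConfigError(
                f"mav_source must be one of {MAV_SOURCES}, got {self.mav_source!r}"
            )
        if self.location_mode not in LOCATION_MODES:
            raise ConfigError(
                f"location_mode must be one of {LOCATION_MODES}, got {self.location_mode!r}"
            )


@dataclass(frozen=True)
class ClassProfile:
    """A known class's MAV, fitted distance tail, and bookkeeping counts."""

    label: str
    mav: np.ndarray
    tail: WeibullTail
    n_samples: int
    tail_size: int

    def __post_init__(self) -> None:
        if not self.n_samples >= self.tail_size >= 2:
            raise ModelBuildError(
                f"class {self.label!r}: need n_samples >= tail_size >= 2, "
                f"got n_samples={self.n_samples}, tail_size={self.tail_size}"
            )
        object.__setattr__(self, "mav", np.asarray(self.mav, dtype=float))


@dataclass(frozen=True)
class OpenSetModel:
    """All class profiles plus the label vocabulary and configuration."""

    vocabulary: tuple[str, ...]
    profiles: tuple[ClassProfile, ...]
    config: OpenMaxConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if tuple(p.label for p in self.profiles) != self.vocabulary:
            raise ModelBuildError("profile labels must match the vocabulary, in order")

    @property
    def n_classes(self) -> int:
        return len(self.vocabulary)

    def mav_matrix(self) -> np.ndarray:
        return np.vstack([p.mav for p in self.profiles])

    # ------------------------------------------------------------ serialization

    def to_dict(self) -> dict:
        return {
            "vocabulary": list(self.vocabulary),
            "classes": {
                p.label: {
                    "mav": [float(v) for v in p.mav],
                    "weibull": {
                        "shape": p.tail.shape,
                        "scale": p.tail.scale,
                        "location": p.tail.location,
                    },
                    "n_samples": p.n_samples,
                    "tail_size": p.tail_size,
                }
                for p in self.profiles
            },
            "config": {
                "beta": self.config.beta,
                "tail_size": self.config.tail_size,
                "threshold": self.config.threshold,
                "decision_mode": self.config.decision_mode,
                "mav_source": self.config.mav_source,
                "location_mode": self.config.location_mode,
                "unknown_label": self.config.unknown_label,
            },
        }

    def to_json(self) -> str:
        # repr-based float formatting round-trips doubles bit-exactly
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_dict(cls, doc: Mapping) -> "OpenSetModel":
        config = OpenMaxConfig(**doc["config"])
        vocabulary = tuple(doc["vocabulary"])
        profiles = tuple(
            ClassProfile(
                label=label,
                mav=np.array(doc["classes"][label]["mav"], dtype=float),
                tail=WeibullTail(**doc["classes"][label]["weibull"]),
                n_samples=doc["classes"][label]["n_samples"],
                tail_size=doc["classes"][label]["tail_size"],
            )
            for label in vocabulary
        )
        return cls(vocabulary=vocabulary, profiles=profiles, config=config)

    @classmethod
    def load(cls, path: str | Path) -> "OpenSetModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class PredictionRecord:
    """One sample's recalibrated scores, OpenMax probabilities, and decision.

    ``probabilities`` has M+1 entries with index 0 the unknown class.
    """

    sample_id: str
    scores: np.ndarray
    probabilities: np.ndarray
    predicted: str


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_mavs(
    records: Iterable[ActivationRecord],
    vocabulary: Sequence[str],
    mav_source: str = "all_samples",
) -> dict[str, tuple[np.ndarray, int]]:
    """Per-class mean activation vector and qualifying-sample count.

    With ``mav_source='correct_only'`` a record qualifies only when the
    argmax of its own vector points at its true class (the convention of the
    original OpenMax literature); ``all_samples`` averages every record of
    the class.
    """
    if mav_source not in MAV_SOURCES:
        raise InvalidArgumentError(
            f"mav_source must be one of {MAV_SOURCES}, got {mav_source!r}"
        )
    index = {label: i for i, label in enumerate(vocabulary)}
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {label: 0 for label in vocabulary}
    for rec in records:
        if rec.label not in index:
            raise InvalidArgumentError(
                f"record {rec.sample_id!r} has label {rec.label!r} outside the vocabulary"
            )
        if mav_source == "correct_only" and int(np.argmax(rec.vector)) != index[rec.label]:
            continue
        if rec.label in sums:
            sums[rec.label] = sums[rec.label] + rec.vector
        else:
            sums[rec.label] = rec.vector.copy()
        counts[rec.label] += 1
    out = {}
    for label in vocabulary:
        if counts[label] == 0:
            raise ModelBuildError(
                f"class {label!r} has no qualifying records (mav_source={mav_source!r})"
            )
        out[label] = (sums[label] / counts[label], counts[label])
    return out


def distance_to_mav(vector: np.ndarray, mav: np.ndarray) -> float:
    """Euclidean distance between an activation vector and a class MAV."""
    vector = np.asarray(vector, dtype=float)
    mav = np.asarray(mav, dtype=float)
    if vector.shape != mav.shape:
        raise InvalidArgumentError(
            f"vector length {vector.shape} does not match MAV length {mav.shape}"
        )
    return float(np.linalg.norm(vector - mav))


def fit_open_set_model(
    records: Iterable[ActivationRecord] | ActivationSet,
    vocabulary: Sequence[str] | None = None,
    config: OpenMaxConfig | None = None,
) -> OpenSetModel:
    """Build MAVs and Weibull distance tails for every known class.

    The tail of class c is fitted on the ``min(config.tail_size, N_c)``
    largest distances between the class's own qualifying records and its
    MAV. The build is deterministic: identical inputs give byte-identical
    serialized models.
    """
    records = list(records)
    config = config or OpenMaxConfig()
    if vocabulary is None:
        labels = {r.label for r in records}
        if config.unknown_label in labels:
            raise ModelBuildError(
                f"training records contain the reserved unknown label {config.unknown_label!r}"
            )
        vocabulary = sorted(labels)
    vocabulary = tuple(vocabulary)
    dims = {r.vector.size for r in records}
    if len(dims) != 1 or dims != {len(vocabulary)}:
        raise ModelBuildError(
            f"activation dimension(s) {sorted(dims)} must equal the vocabulary size "
            f"{len(vocabulary)} (one activation per known class)"
        )
    mavs = compute_mavs(records, vocabulary, config.mav_source)
    index = {label: i for i, label in enumerate(vocabulary)}
    profiles = []
    for label in vocabulary:
        mav, n_c = mavs[label]
        if config.mav_source == "correct_only":
            own = [
                r.vector
                for r in records
                if r.label == label and int(np.argmax(r.vector)) == index[label]
            ]
        else:
            own = [r.vector for r in records if r.label == label]
        dist = np.linalg.norm(np.vstack(own) - mav, axis=1)
        eta = min(config.tail_size, n_c)
        if eta < 2:
            raise ModelBuildError(
                f"class {label!r} has only {n_c} qualifying record(s); need at least 2"
            )
        try:
            tail = fit_weibull_tail(dist, eta, config.location_mode)
        except DegenerateTailError as exc:
            raise ModelBuildError(f"class {label!r}: {exc}") from exc
        profiles.append(
            ClassProfile(label=label, mav=mav, tail=tail, n_samples=n_c, tail_size=eta)
        )
    return OpenSetModel(vocabulary=vocabulary, profiles=tuple(profiles), config=config)


def recalibrated_scores(vector: np.ndarray, model: OpenSetModel) -> np.ndarray:
    """Per-class scores ``r_c = 1 - CDF_c(||z - MAV_c||)``, each in [0, 1]."""
    vector = np.asarray(vector, dtype=float)
    out = np.empty(model.n_classes)
    for i, p in enumerate(model.profiles):
        out[i] = 1.0 - weibull_cdf(distance_to_mav(vector, p.mav), p.tail)
    return out


def predict_score_threshold(
    scores: np.ndarray,
    threshold: float,
    vocabulary: Sequence[str],
    unknown_label: str = UNKNOWN_LABEL,
) -> str:
    """Unknown when ``max(r_c) < ε``, else the argmax class (ties: lowest index)."""
    scores = np.asarray(scores, dtype=float)
    if scores.max() < threshold:
        return unknown_label
    return vocabulary[int(np.argmax(scores))]


def openmax_probabilities(
    vector: np.ndarray, model: OpenSetModel, literal_exponential: bool = False
) -> np.ndarray:
    """OpenMax probabilities over M+1 classes, index 0 the synthetic unknown.

    The β top-ranked activations are down-weighted by
    ``θ = 1 - ((β - j)/β) * CDF_c(distance)`` (j = 1 is the top rank), the
    removed mass ``sum_j a_j (1 - θ_j)`` becomes the unknown activation, and
    a max-stabilized softmax over the M+1 augmented activations yields the
    probabilities. ``literal_exponential=True`` swaps the Weibull CDF weight
    for a raw exponential of the distance ratio — a diagnostic form that is
    unbounded and not a probability; it exists only for comparison.
    """
    vector = np.asarray(vector, dtype=float)
    m = model.n_classes
    if vector.size != m:
        raise InvalidArgumentError(
            f"activation length {vector.size} does not match vocabulary size {m}"
        )
    beta = model.config.beta if model.config.beta is not None else m
    if not 0 <= beta <= m:
        raise ConfigError(f"beta must be in [0, {m}], got {beta}")
    order = np.argsort(-vector, kind="stable")
    theta = np.ones(m)
    for j in range(1, beta + 1):
        c = int(order[j - 1])
        p = model.profiles[c]
        d = distance_to_mav(vector, p.mav)
        if literal_exponential:
            weight = np.exp(((d - p.tail.location) / p.tail.scale) ** p.tail.shape)
        else:
            weight = weibull_cdf(d, p.tail)
        theta[c] = 1.0 - ((beta - j) / beta) * weight
    adjusted = vector * theta
    unknown_activation = float(np.dot(vector, 1.0 - theta))
    logits = np.concatenate(([unknown_activation], adjusted))
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def predict_openmax(
    probabilities: np.ndarray,
    threshold: float,
    vocabulary: Sequence[str],
    unknown_label: str = UNKNOWN_LABEL,
) -> str:
    """Reject when the unknown class wins or the winner is below ε."""
    probabilities = np.asarray(probabilities, dtype=float)
    c_star = int(np.argmax(probabilities))
    if c_star == 0 or probabilities[c_star] < threshold:
        return unknown_label
    return vocabulary[c_star - 1]


def predict_record(
    record: ActivationRecord,
    model: OpenSetModel,
    decision_mode: str | None = None,
    threshold: float | None = None,
) -> PredictionRecord:
    """Scores, probabilities, and the configured decision for one sample."""
    mode = decision_mode or model.config.decision_mode
    eps = model.config.threshold if threshold is None else threshold
    scores = recalibrated_scores(record.vector, model)
    probabilities = openmax_probabilities(record.vector, model)
    if mode == "score_threshold":
        predicted = predict_score_threshold(
            scores, eps, model.vocabulary, model.config.unknown_label
        )
    elif mode == "openmax":
        predicted = predict_openmax(
            probabilities, eps, model.vocabulary, model.config.unknown_label
        )
    else:
        raise ConfigError(f"decision_mode must be one of {DECISION_MODES}, got {mode!r}")
    return PredictionRecord(record.sample_id, scores, probabilities, predicted)


def predict_set(
    records: Iterable[ActivationRecord] | ActivationSet,
    model: OpenSetModel,
    decision_mode: str | None = None,
    threshold: float | None = None,
) -> list[PredictionRecord]:
    return [predict_record(r, model, decision_mode, threshold) for r in records]


def predictions_frame(predictions: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Tabular prediction output: sample_id, predicted, max_score, p_unknown, p_class_*."""
    if not predictions:
        raise InvalidArgumentError("no predictions to tabulate")
    m = predictions[0].scores.size
    rows = []
    for p in predictions:
        rows.append(
            (p.sample_id, p.predicted, float(p.scores.max()), float(p.probabilities[0]))
            + tuple(float(x) for x in p.probabilities[1:])
        )
    cols = ["sample_id", "predicted", "max_score", "p_unknown"] + [
        f"p_class_{i}" for i in range(m)
    ]
    return pd.DataFrame(rows, columns=cols)


def tail_diagnostics(
    model: OpenSetModel,
    records: Iterable[ActivationRecord] | ActivationSet,
    quantiles: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
) -> pd.DataFrame:
    """Empirical distance deciles vs fitted Weibull CDF, per class.

    For a well-fitted tail the ``fitted_cdf`` column tracks the
    ``quantile`` column over the tail region — the tabular counterpart of
    per-class Weibull diagnostic plots.
    """
    by_label: dict[str, list[np.ndarray]] = {label: [] for label in model.vocabulary}
    for r in records:
        if r.label in by_label:
            by_label[r.label].append(r.vector)
    rows = []
    for profile in model.profiles:
        vecs = by_label[profile.label]
        if not vecs:
            continue
        dist = np.linalg.norm(np.vstack(vecs) - profile.mav, axis=1)
        for q in quantiles:
            dq = float(np.quantile(dist, q))
            rows.append((profile.label, float(q), dq, weibull_cdf(dq, profile.tail)))
    return pd.DataFrame(rows, columns=["label", "quantile", "distance", "fitted_cdf"])
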