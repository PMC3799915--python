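"""Spatio-spectral filter estimation on the delay-embedded space.

The method generalises common spatial patterns (CSP).  CSP finds spatial
weight vectors ``w`` extremising the generalised Rayleigh quotient

    lambda(w) = w' S1 w / w' (S1 + S2) w,

where ``S1, S2`` are the two class covariance matrices; eigenvalues near 1
mean high condition-1 variance, near 0 high condition-2 variance.  Here the
same problem is solved on the delay-embedded data, so each eigenvector
jointly encodes one spatial filter per delay — equivalently one
channel-specific FIR filter per channel.  Because the augmented dimension
``D = C * (2k+1)`` can rival or exceed the number of samples, the problem
is regularised with a ridge term ``eps * I`` on both sides:

    (S1 + eps I) w = lambda (S1 + S2 + 2 eps I) w,

which keeps every eigenvalue strictly inside (0, 1) and preserves the CSP
symmetry lambda <-> 1 - lambda under swapping the class roles.  With
``k = 0`` the method reduces exactly to regularised CSP.

Per-trial covariances are trace-normalised before averaging (standard CSP
practice), so ``eps`` is comparable across datasets; the grid
``{1e-4, 1e-5, 1e-6}`` and the fixed default ``eps = 1e-5`` presume this
scaling.  Features are the log-variances of the trials projected onto the
``m`` leading and ``m`` trailing eigenvectors.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .delay_embedding import AugmentedEpochs, embed
from .epochs_io import EEGEpochs
from .exceptions import NumericalError, ParameterError, ValidationError

__all__ = [
    "ClassCovariance",
    "SpatialSpectralModel",
    "FeatureMatrix",
    "class_covariances",
    "solve_regularized_gevd",
    "fit",
    "extract_features",
    "save_model",
    "load_model",
    "DEFAULT_K",
    "DEFAULT_EPSILON",
    "DEFAULT_M_MI",
    "DEFAULT_M_RSVP",
]

# fixed-parameter defaults and pair counts for the two protocols
DEFAULT_K = 5
DEFAULT_EPSILON = 1e-5
DEFAULT_M_MI = 3
DEFAULT_M_RSVP = 2

MODEL_FORMAT_VERSION = "1"


@dataclass
class ClassCovariance:
    """Trace-normalised mean covariance of one condition on the augmented space."""

    matrix: np.ndarray
    condition: int
    n_trials_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        M = self.matrix
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValidationError(f"matrix: expected square, got shape {M.shape}")
        if not np.allclose(M, M.T, atol=1e-12, rtol=0):
            raise ValidationError("matrix: not symmetric to 1e-12")
        tr = np.trace(M)
        if abs(tr - 1.0) > 1e-9:
            raise ValidationError(f"matrix: trace {tr} not normalised to 1")
        w = np.linalg.eigvalsh(M)
        if w.min() < -1e-10 * tr:
            raise ValidationError(f"matrix: not PSD (min eigenvalue {w.min()})")


@dataclass
class SpatialSpectralModel:
    """A fitted bank of 2m spatial-FIR filters with their eigenvalues.

    ``W`` has shape ``(D, 2m)`` with ``D = n_channels * (2k+1)``.  Columns
    ``0..m-1`` carry the m largest eigenvalues in descending order (high
    condition-1 variance); columns ``m..2m-1`` the m smallest in ascending
    order.  Each column has unit Euclidean norm with its largest-magnitude
    entry positive, fixing the sign/scale ambiguity of eigenvectors.
    """

    W: np.ndarray
    eigvals: np.ndarray
    k: int
    epsilon: float
    m: int
    n_channels: int
    channel_names: list[str]
    fs: float
    classes: tuple = (1, 2)
    classifier: dict | None = None  # optional linear read-out (coef, intercept)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.eigvals = np.asarray(self.eigvals, dtype=np.float64)
        D = self.n_channels * (2 * self.k + 1)
        if self.W.shape != (D, 2 * self.m):
            raise ValidationError(
                f"W: expected shape ({D}, {2 * self.m}), got {self.W.shape}"
            )
        if self.eigvals.shape != (2 * self.m,):
            raise ValidationError("eigvals: length must be 2m")


@dataclass
class FeatureMatrix:
    """Log-variance features: one row per trial, one column per filter."""

    values: np.ndarray
    filter_ids: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values: contains non-finite entries")


def _condition_split(labels: np.ndarray):
    """Map the (at most two) label values onto conditions 1 and 2.

    The smaller label value becomes condition 1.
    """
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValidationError(
            f"labels: need exactly two classes, found values {uniq.tolist()}"
        )
    return uniq[0], uniq[1]


def class_covariances(
    aug: AugmentedEpochs, labels: np.ndarray | None = None
) -> tuple[ClassCovariance, ClassCovariance]:
    """Per-condition mean of trace-normalised per-trial covariances.

    Each trial contributes ``X X' / trace(X X')``; the arithmetic mean over a
    condition's trials is renormalised to trace 1.
    """
    labels = aug.labels if labels is None else np.asarray(labels)
    if labels.shape[0] != aug.n_trials:
        raise ValidationError("labels: length does not match n_trials")
    l1, l2 = _condition_split(labels)
    out = []
    for cond, lab in ((1, l1), (2, l2)):
        idx = np.where(labels == lab)[0]
        if len(idx) == 0:
            raise ValidationError(f"labels: condition {cond} has zero trials")
        acc = np.zeros((aug.n_rows, aug.n_rows))
        for t in idx:
            X = aug.data[t]
            S = X @ X.T
            tr = np.trace(S)
            if tr <= 0:
                raise ValidationError(
                    f"data: trial {t} has zero total power (trace 0)"
                )
            acc += S / tr
        acc /= len(idx)
        acc /= np.trace(acc)
        acc = (acc + acc.T) / 2.0
        out.append(ClassCovariance(matrix=acc, condition=cond, n_trials_used=len(idx)))
    return out[0], out[1]


def _fix_sign_and_norm(V: np.ndarray) -> np.ndarray:
    """Unit-normalise columns and make each column's largest-|entry| positive."""
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    piv = np.abs(V).argmax(axis=0)
    signs = np.sign(V[piv, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def solve_regularized_gevd(S1, S2, epsilon: float):
    """Solve ``(S1 + eps I) w = lambda (S1 + S2 + 2 eps I) w``.

    Parameters may be :class:`ClassCovariance` objects or plain symmetric
    arrays.  Returns ``(eigvals, eigvecs)`` with eigenvalues sorted
    descending and eigenvectors as unit-norm, sign-fixed columns aligned
    with them.  With ``eps > 0`` the right-hand matrix is positive definite
    and every eigenvalue lies strictly in (0, 1); with ``eps = 0`` a
    singular composite matrix raises :class:`NumericalError`.
    """
    A0 = S1.matrix if isinstance(S1, ClassCovariance) else np.asarray(S1, float)
    C0 = S2.matrix if isinstance(S2, ClassCovariance) else np.asarray(S2, float)
    if A0.shape != C0.shape or A0.ndim != 2 or A0.shape[0] != A0.shape[1]:
        raise ValidationError(
            f"covariances: mismatched shapes {A0.shape} vs {C0.shape}"
        )
    for name, M in (("S1", A0), ("S2", C0)):
        if not np.allclose(M, M.T, atol=1e-10, rtol=0):
            raise ValidationError(f"{name}: not symmetric")
    if epsilon < 0:
        raise ParameterError(f"epsilon: must be >= 0, got {epsilon}")
    D = A0.shape[0]
    A = A0 + epsilon * np.eye(D)
    B = A0 + C0 + 2 * epsilon * np.eye(D)
    if epsilon == 0:
        # eigh requires B positive definite; detect the singular failure mode
        min_eig = np.linalg.eigvalsh(B).min()
        if min_eig <= 1e-12 * np.trace(B):
            raise NumericalError(
                "composite covariance S1 + S2 is singular with epsilon = 0; "
                "set epsilon > 0 to regularize the eigenproblem"
            )
    try:
        vals, vecs = scipy.linalg.eigh(A, B)
    except scipy.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise NumericalError(f"generalized eigendecomposition failed: {e}") from e
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = _fix_sign_and_norm(vecs[:, order])
    return vals, vecs


def fit(
    epochs: EEGEpochs,
    k: int = DEFAULT_K,
    epsilon: float = DEFAULT_EPSILON,
    m: int = DEFAULT_M_MI,
) -> SpatialSpectralModel:
    """Fit the spatio-spectral filter bank on labelled epochs.

    Pipeline: delay-embed with half-order ``k`` -> class covariances ->
    regularised GEVD -> keep the ``m`` leading and ``m`` trailing
    eigenvectors.  ``k = 0`` is exactly regularised CSP on the raw channels.
    """
    if m < 1:
        raise ParameterError(f"m: must be >= 1, got {m}")
    D = epochs.n_channels * (2 * k + 1)
    if 2 * m > D:
        raise ParameterError(
            f"m: 2m = {2 * m} filters requested but the augmented space has "
            f"only D = {D} dimensions"
        )
    aug = embed(epochs, k)
    S1, S2 = class_covariances(aug)
    vals, vecs = solve_regularized_gevd(S1, S2, epsilon)
    lead = list(range(m))                     # m largest, descending
    trail = [D - 1 - j for j in range(m)]     # m smallest, ascending
    cols = lead + trail
    uniq = np.unique(epochs.labels)
    return SpatialSpectralModel(
        W=vecs[:, cols],
        eigvals=vals[cols],
        k=k,
        epsilon=float(epsilon),
        m=m,
        n_channels=epochs.n_channels,
        channel_names=list(epochs.channel_names),
        fs=epochs.fs,
        classes=(int(uniq[0]), int(uniq[1])),
    )


def extract_features(model: SpatialSpectralModel, epochs: EEGEpochs) -> FeatureMatrix:
    """Log-variance of each trial projected onto each model column.

    A projected series with zero variance raises an error naming the trial
    and filter rather than silently producing ``-inf``.
    """
    if epochs.n_channels != model.n_channels:
        raise ValidationError(
            f"epochs: {epochs.n_channels} channels but model expects "
            f"{model.n_channels}"
        )
    if epochs.fs != model.fs:
        raise ValidationError(
            f"epochs: fs {epochs.fs} does not match model fs {model.fs}"
        )
    aug = embed(epochs, model.k)
    # (trials, 2m, T') projections
    proj = np.einsum("dj,tds->tjs", model.W, aug.data)
    var = proj.var(axis=2, ddof=1)
    zero = np.argwhere(var <= 0)
    if zero.size:
        t, j = zero[0]
        raise ValidationError(
            f"data: projected series of trial {t} on filter {j} has zero "
            "variance; log-variance is undefined"
        )
    return FeatureMatrix(values=np.log(var), filter_ids=list(range(2 * model.m)))


# ---------------------------------------------------------------------------
# Serialization: one JSON document, numeric payload base64-embedded.
# ---------------------------------------------------------------------------

def _encode_array(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype=np.float64)
    return {
        "dtype": "float64",
        "shape": list(a.shape),
        "data": base64.b64encode(a.tobytes()).decode("ascii"),
    }


def _decode_array(d: dict) -> np.ndarray:
    raw = base64.b64decode(d["data"])
    return np.frombuffer(raw, dtype=d["dtype"]).reshape(d["shape"]).copy()


def save_model(model: SpatialSpectralModel, path) -> None:
    """Write the model (and optional linear read-out) as a single JSON file.

    The byte stream is deterministic for a given model, so identical fits
    produce identical files.
    """
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "k": model.k,
        "epsilon": model.epsilon,
        "m": model.m,
        "n_channels": model.n_channels,
        "channel_names": model.channel_names,
        "fs": model.fs,
        "classes": list(model.classes),
        "eigvals": _encode_array(model.eigvals),
        "W": _encode_array(model.W),
    }
    if model.classifier is not None:
        doc["classifier"] = {
            "coef": _encode_array(np.asarray(model.classifier["coef"])),
            "intercept": float(model.classifier["intercept"]),
            "classes": [int(c) for c in model.classifier["classes"]],
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def load_model(path) -> SpatialSpectralModel:
    """Read a model written by :func:`save_model`."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("k", "epsilon", "m", "n_channels", "fs", "W", "eigvals"):
        if key not in doc:
            raise ValidationError(f"{path}: model file missing field '{key}'")
    clf = None
    if "classifier" in doc:
        clf = {
            "coef": _decode_array(doc["classifier"]["coef"]),
            "intercept": doc["classifier"]["intercept"],
            "classes": doc["classifier"]["classes"],
        }
    return SpatialSpectralModel(
        W=_decode_array(doc["W"]),
        eigvals=_decode_array(doc["eigvals"]),
        k=int(doc["k"]),
        epsilon=float(doc["epsilon"]),
        m=int(doc["m"]),
        n_channels=int(doc["n_channels"]),
        channel_names=list(doc.get("channel_names", [])),
        fs=float(doc["fs"]),
        classes=tuple(doc.get("classes", (1, 2))),
        classifier=clf,
    )
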