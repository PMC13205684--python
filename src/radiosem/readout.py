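"""Linear semantic readouts and linear arrhythmia diagnosis.

Everything here is deliberately linear in the 64 semantic factors:
ordinary least squares (ridge fallback) for the factor-to-semantic
readouts (ventricular rate, PR, QT), and multinomial logistic regression
for the factor-to-disease projection, with recording-level aggregation
by mean segment probability. Factor perturbation sweeps visualize how a
single factor drives the decoded ECG and radio waveforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge

READOUT_TARGETS = ("ventricular_rate", "pr_ms", "qt_ms")
DIAGNOSIS_CLASSES = ("NORMAL", "AF", "PB")


class SubjectOverlapError(RuntimeError):
    """Raised when held-out prediction sees a training subject."""


@dataclass
class LinearReadout:
    """Per-target affine maps from the factor space to semantic values."""

    weights: dict[str, np.ndarray]        # target -> (latent_dim,)
    intercepts: dict[str, float]
    fit_metadata: dict = field(default_factory=dict)
    fit_subjects: frozenset = frozenset()

    @property
    def target_names(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def predict(self, Z: np.ndarray) -> dict[str, np.ndarray]:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        out = {}
        for name, w in self.weights.items():
            if Z.shape[1] != w.size:
                raise ValueError("factor dimension mismatch")
            out[name] = Z @ w + self.intercepts[name]
        return out

    def predict_heldout(self, Z: np.ndarray, subject_ids) -> dict[str, np.ndarray]:
        """Predict while enforcing subject-disjoint evaluation."""
        overlap = self.fit_subjects & set(subject_ids)
        if overlap:
            raise SubjectOverlapError(
                f"held-out prediction overlaps training subjects: {sorted(overlap)[:5]}"
            )
        return self.predict(Z)

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": {k: v.tolist() for k, v in self.weights.items()},
                "intercepts": self.intercepts,
                "fit_metadata": self.fit_metadata,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearReadout":
        d = json.loads(text)
        return cls(
            weights={k: np.asarray(v) for k, v in d["weights"].items()},
            intercepts=d["intercepts"],
            fit_metadata=d.get("fit_metadata", {}),
        )


def fit_linear_readout(
    Z: np.ndarray,
    targets: dict[str, np.ndarray],
    subject_ids=None,
    ridge_lambda: float | None = None,
    seed: int = 0,
) -> LinearReadout:
    """Ordinary least squares per target; ridge (lambda=1e-3) fallback
    when the design is under-determined or rank-deficient."""
    Z = np.asarray(Z, dtype=float)
    n, d = Z.shape
    use_ridge = ridge_lambda is not None
    if not use_ridge and n <= d:
        use_ridge, ridge_lambda = True, 1e-3
    if not use_ridge and np.linalg.matrix_rank(np.c_[Z, np.ones(n)]) < d + 1:
        raise np.linalg.LinAlgError(
            "rank-deficient factor matrix; pass ridge_lambda (e.g. 1e-3)"
        )
    weights, intercepts = {}, {}
    for name, y in targets.items():
        y = np.asarray(y, dtype=float)
        if y.size != n:
            raise ValueError(f"target {name}: length mismatch")
        model = Ridge(alpha=ridge_lambda) if use_ridge else LinearRegression()
        model.fit(Z, y)
        weights[name] = model.coef_.copy()
        intercepts[name] = float(model.intercept_)
    return LinearReadout(
        weights=weights,
        intercepts=intercepts,
        fit_metadata={"n": n, "ridge": ridge_lambda if use_ridge else None, "seed": seed},
        fit_subjects=frozenset(subject_ids or ()),
    )


def predict_readout(model: LinearReadout, Z: np.ndarray) -> dict[str, np.ndarray]:
    return model.predict(Z)


@dataclass
class DiagnosisModel:
    """Linear (logistic) projection from factors to rhythm classes."""

    weights: np.ndarray                   # (classes, latent_dim)
    intercepts: np.ndarray
    classes: tuple[str, ...]
    decision_threshold: float = 0.5
    factor_sd: np.ndarray | None = None
    fit_subjects: frozenset = frozenset()

    def segment_probabilities(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        logits = Z @ self.weights.T + self.intercepts
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def attribution(self) -> dict[str, np.ndarray]:
        """Per-class factor attribution: weight x factor SD (decision pathway)."""
        sd = self.factor_sd if self.factor_sd is not None else np.ones(self.weights.shape[1])
        return {c: self.weights[i] * sd for i, c in enumerate(self.classes)}

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "intercepts": self.intercepts.tolist(),
                "classes": list(self.classes),
                "decision_threshold": self.decision_threshold,
                "factor_sd": None if self.factor_sd is None else self.factor_sd.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DiagnosisModel":
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"]),
            intercepts=np.asarray(d["intercepts"]),
            classes=tuple(d["classes"]),
            decision_threshold=d["decision_threshold"],
            factor_sd=None if d["factor_sd"] is None else np.asarray(d["factor_sd"]),
        )


def fit_diagnosis(
    Z: np.ndarray,
    labels: np.ndarray,
    subject_ids=None,
    classes: tuple[str, ...] = DIAGNOSIS_CLASSES,
    seed: int = 0,
) -> DiagnosisModel:
    """Multinomial logistic regression on segment factors.

    ``labels`` are per-segment class names (each segment inherits its
    recording's label).
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    present = [c for c in classes if np.any(labels == c)]
    if len(present) < 2:
        raise ValueError("diagnosis training needs at least two classes")
    y = np.array([present.index(l) for l in labels])
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(Z, y)
    if len(present) == 2:
        w = np.vstack([-clf.coef_[0], clf.coef_[0]]) / 2
        b = np.array([-clf.intercept_[0], clf.intercept_[0]]) / 2
    else:
        w, b = clf.coef_, clf.intercept_
    return DiagnosisModel(
        weights=w,
        intercepts=b,
        classes=tuple(present),
        factor_sd=Z.std(axis=0),
        fit_subjects=frozenset(subject_ids or ()),
    )


def predict_diagnosis(
    model: DiagnosisModel,
    Z_by_recording: dict[str, np.ndarray],
    enforce_disjoint: bool = False,
) -> dict[str, dict[str, float]]:
    """Recording-level class probabilities: mean over segment probabilities.

    A class is called positive when its mean probability reaches the
    decision threshold.
    """
    if enforce_disjoint:
        overlap = model.fit_subjects & set(Z_by_recording)
        if overlap:
            raise SubjectOverlapError(
                f"recordings overlap training subjects: {sorted(overlap)[:5]}"
            )
    out = {}
    for rec_id, Z in Z_by_recording.items():
        probs = model.segment_probabilities(Z).mean(axis=0)
        out[rec_id] = {c: float(probs[i]) for i, c in enumerate(model.classes)}
    return out


def call_recordings(
    probabilities: dict[str, dict[str, float]], threshold: float = 0.5
) -> dict[str, str]:
    """Hard recording-level call: argmax class, requiring threshold for
    the arrhythmia classes."""
    calls = {}
    for rec_id, probs in probabilities.items():
        best = max(probs, key=probs.get)
        calls[rec_id] = best if probs[best] >= threshold or best == "NORMAL" else "NORMAL"
    return calls


def top_correlated_factor(Z: np.ndarray, values: np.ndarray) -> tuple[int, float]:
    """Factor index maximizing |Pearson r| with the semantic values.

    Constant (zero-variance) factors are excluded; ties break toward the
    lowest index.
    """
    Z = np.asarray(Z, dtype=float)
    values = np.asarray(values, dtype=float)
    if Z.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    best_idx, best_r = -1, -1.0
    for j in range(Z.shape[1]):
        col = Z[:, j]
        if np.ptp(col) == 0 or np.ptp(values) == 0:
            continue
        r = float(np.corrcoef(col, values)[0, 1])
        if np.isnan(r):
            continue
        if abs(r) > best_r + 1e-15:
            best_idx, best_r = j, abs(r)
    if best_idx < 0:
        raise ValueError("no non-constant factor available")
    r_signed = float(np.corrcoef(Z[:, best_idx], values)[0, 1])
    return best_idx, r_signed


def perturb_factor(
    z: np.ndarray,
    index: int,
    scales,
    ecg_space,
    radio_results,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Decode z with factor ``index`` swept over ``scales`` through both
    frozen decoders; returns (ecg_view, radio_view) per scale."""
    z = np.asarray(z, dtype=float).ravel()
    if index >= z.size:
        raise ValueError("factor index out of range")
    if ecg_space.config.latent_dim != z.size or radio_results.config.latent_dim != z.size:
        raise ValueError("frozen-model latent dimension mismatch")
    out = []
    from . import nn  # local import to keep module import light

    for s in scales:
        zz = z.copy()
        zz[index] = s
        # radio factors live in the standardized semantic space; map back
        # before running the ECG decoder
        zz_e = radio_results._unstandardize(zz) if hasattr(radio_results, "_unstandardize") else zz
        ecg_view = ecg_space.decode(zz_e)
        radio_view = (
            radio_results.net.decoder(nn.Tensor(zz[None].astype(np.float32))).data[0]
            * radio_results.config.motion_scale
        )
        out.append((ecg_view, radio_view))
    return out


def readout_correlations(
    pred: dict[str, np.ndarray], truth: dict[str, np.ndarray]
) -> dict[str, tuple[float, float]]:
    """Pearson (R, p) per semantic target."""
    out = {}
    for name in pred:
        r, p = sp_stats.pearsonr(pred[name], truth[name])
        out[name] = (float(r), float(p))
    return out
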