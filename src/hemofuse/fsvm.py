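"""Fuzzy support vector machine (FSVM).

A soft-margin SVM in which every training point carries a fuzzy
membership s_i in [sigma, 1]: the primal penalises C * s_i * xi_i instead
of C * xi_i, so noisy or atypical points (low membership) buy slack more
cheaply and bend the decision surface less.  The dual is the standard
C-SVM dual with per-sample box caps:

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.   sum_i y_i a_i = 0,    0 <= a_i <= s_i * C

With s_i = 1 everywhere the model degenerates to the ordinary C-SVM.

The dual is solved by a maximal-violating-pair SMO (the working-set
strategy of LIBSVM): at each step the most KKT-violating pair is updated
analytically, the gradient is maintained incrementally, and iteration
stops when the duality-gap surrogate m(a) - M(a) drops below tolerance.
Memberships default to the centroid-distance scheme
s_i = 1 - d_i / (d_max + delta), clamped to [sigma, 1]: points far from
their class centroid — the likeliest outliers — get the smallest say.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FSVMHyperparams",
    "FSVMModel",
    "MulticlassFSVM",
    "assign_memberships",
    "kernel_matrix",
    "train_fsvm",
    "train_multiclass",
]

MEMBERSHIP_SCHEMES = ("centroid-linear", "uniform")


@dataclass(frozen=True)
class FSVMHyperparams:
    """Trade-off C, kernel spec and solver tolerances."""

    C: float = 10.0
    kernel: str = "rbf"            # linear | rbf | polynomial
    gamma: float | None = None     # rbf width; None -> 1/(n_features * var(X))
    degree: int = 3
    coef0: float = 1.0
    tol: float = 1e-8              # KKT feasibility tolerance
    max_passes: int = 200_000

    def validate(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel not in ("linear", "rbf", "polynomial"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def resolve_gamma(hp: FSVMHyperparams, X: np.ndarray) -> float:
    if hp.gamma is not None:
        return hp.gamma
    var = float(np.var(X))
    return 1.0 / (X.shape[1] * var) if var > 0 else 1.0 / X.shape[1]


def kernel_matrix(hp: FSVMHyperparams, X: np.ndarray, Y: np.ndarray | None = None,
                  gamma: float | None = None) -> np.ndarray:
    Y = X if Y is None else Y
    if hp.kernel == "linear":
        return X @ Y.T
    if hp.kernel == "polynomial":
        g = gamma if gamma is not None else resolve_gamma(hp, X)
        return (g * (X @ Y.T) + hp.coef0) ** hp.degree
    g = gamma if gamma is not None else resolve_gamma(hp, X)
    sq = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    return np.exp(-g * np.maximum(sq, 0.0))


def assign_memberships(
    points: np.ndarray,
    labels: np.ndarray,
    scheme: str = "centroid-linear",
    sigma: float = 0.05,
) -> np.ndarray:
    """Fuzzy memberships s_i in [sigma, 1] per the chosen scheme."""
    if scheme not in MEMBERSHIP_SCHEMES:
        raise ValueError(f"unknown membership scheme {scheme!r}")
    X = np.asarray(points, dtype=float)
    y = np.asarray(labels)
    s = np.ones(X.shape[0])
    if scheme == "uniform":
        return s
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls!r} has no samples")
        centroid = X[idx].mean(axis=0)
        d = np.linalg.norm(X[idx] - centroid, axis=1)
        d_max = d.max()
        delta = 1e-6 * d_max if d_max > 0 else 1.0
        s[idx] = 1.0 - d / (d_max + delta)
    return np.clip(s, sigma, 1.0)


@dataclass
class FSVMModel:
    """Trained binary FSVM: dual coefficients, bias and kernel closure."""

    alpha: np.ndarray
    bias: float
    support_idx: np.ndarray
    X: np.ndarray
    y: np.ndarray
    memberships: np.ndarray
    hp: FSVMHyperparams
    gamma: float
    scheme: str = "centroid-linear"
    degenerate: bool = False

    @property
    def w(self) -> np.ndarray:
        """Explicit normal vector (linear kernel only)."""
        if self.hp.kernel != "linear":
            raise ValueError("explicit w only defined for the linear kernel")
        return (self.alpha * self.y) @ self.X

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = kernel_matrix(self.hp, self.X, X, gamma=self.gamma)
        return (self.alpha * self.y) @ K + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {-1, +1}; sign(0) -> +1 by convention."""
        return np.where(self.decision_function(X) >= 0.0, 1, -1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": 1,
                "alpha": self.alpha.tolist(),
                "bias": self.bias,
                "support_idx": self.support_idx.tolist(),
                "X": self.X.tolist(),
                "y": self.y.tolist(),
                "memberships": self.memberships.tolist(),
                "kernel": {
                    "name": self.hp.kernel,
                    "gamma": self.gamma,
                    "degree": self.hp.degree,
                    "coef0": self.hp.coef0,
                },
                "C": self.hp.C,
                "membership_scheme": self.scheme,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "FSVMModel":
        d = json.loads(payload)
        hp = FSVMHyperparams(
            C=d["C"],
            kernel=d["kernel"]["name"],
            gamma=d["kernel"]["gamma"],
            degree=d["kernel"]["degree"],
            coef0=d["kernel"]["coef0"],
        )
        return cls(
            alpha=np.asarray(d["alpha"]),
            bias=d["bias"],
            support_idx=np.asarray(d["support_idx"], dtype=int),
            X=np.asarray(d["X"]),
            y=np.asarray(d["y"]),
            memberships=np.asarray(d["memberships"]),
            hp=hp,
            gamma=d["kernel"]["gamma"],
            scheme=d["membership_scheme"],
        )


def _smo(Q: np.ndarray, y: np.ndarray, cap: np.ndarray, tol: float,
         max_passes: int) -> np.ndarray:
    """Maximal-violating-pair SMO for the dual with per-sample caps."""
    n = y.size
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of 1/2 a'Qa - e'a

    for _ in range(max_passes):
        yg = -y * grad
        up = ((y > 0) & (alpha < cap - 1e-14)) | ((y < 0) & (alpha > 1e-14))
        low = ((y < 0) & (alpha < cap - 1e-14)) | ((y > 0) & (alpha > 1e-14))
        if not up.any() or not low.any():
            break
        i = int(np.flatnonzero(up)[np.argmax(yg[up])])
        j = int(np.flatnonzero(low)[np.argmin(yg[low])])
        if yg[i] - yg[j] < tol:
            break
        quad = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        if quad <= 1e-15:
            quad = 1e-12
        d = (yg[i] - yg[j]) / quad
        # move along a_i += y_i*d, a_j -= y_j*d keeping sum y*a fixed
        if y[i] > 0:
            d = min(d, cap[i] - alpha[i])
        else:
            d = min(d, alpha[i])
        if y[j] > 0:
            d = min(d, alpha[j])
        else:
            d = min(d, cap[j] - alpha[j])
        if d <= 0:
            break
        da_i, da_j = y[i] * d, -y[j] * d
        alpha[i] += da_i
        alpha[j] += da_j
        grad += Q[:, i] * da_i + Q[:, j] * da_j
    return alpha


def train_fsvm(
    X: np.ndarray,
    y: np.ndarray,
    memberships: np.ndarray | None = None,
    hp: FSVMHyperparams | None = None,
    scheme: str = "centroid-linear",
    sigma: float = 0.05,
) -> FSVMModel:
    """Solve the membership-capped dual and recover the bias.

    ``y`` must be in {-1, +1} with both labels present.  If
    ``memberships`` is None they are assigned by ``scheme``.
    """
    hp = hp or FSVMHyperparams()
    hp.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must contain both -1 and +1")
    if memberships is None:
        memberships = assign_memberships(X, y, scheme=scheme, sigma=sigma)
    s = np.asarray(memberships, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("memberships must lie in [0, 1]")

    gamma = resolve_gamma(hp, X)
    K = kernel_matrix(hp, X, gamma=gamma)
    if not np.all(np.isfinite(K)):
        raise FloatingPointError("kernel matrix is not finite")
    Q = (y[:, None] * y[None, :]) * K
    cap = s * hp.C
    alpha = _smo(Q, y, cap, hp.tol, hp.max_passes)

    f = (alpha * y) @ K  # decision values without bias
    free = (alpha > hp.tol) & (alpha < cap - hp.tol)
    degenerate = False
    if free.any():
        bias = float(np.mean(y[free] - f[free]))
    else:
        # midpoint rule over the KKT interval
        up = ((y > 0) & (alpha < cap - hp.tol)) | ((y < 0) & (alpha > hp.tol))
        low = ((y < 0) & (alpha < cap - hp.tol)) | ((y > 0) & (alpha > hp.tol))
        yf = y - f
        hi = np.max(yf[up]) if up.any() else 0.0
        lo = np.min(yf[low]) if low.any() else 0.0
        bias = float((hi + lo) / 2.0)
        degenerate = True
        warnings.warn("no free support vectors; bias set by midpoint rule")

    support = np.flatnonzero(alpha > hp.tol)
    return FSVMModel(
        alpha=alpha, bias=bias, support_idx=support, X=X, y=y,
        memberships=s, hp=hp, gamma=gamma, scheme=scheme, degenerate=degenerate,
    )


@dataclass
class MulticlassFSVM:
    """One-vs-rest ensemble; prediction is the argmax decision value."""

    classes: list
    models: list = field(default_factory=list)

    def decision_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.decision_function(X) for m in self.models])

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.decision_matrix(X), axis=1)  # ties -> class order
        return np.asarray(self.classes, dtype=object)[idx]


def train_multiclass(
    X: np.ndarray,
    labels: np.ndarray,
    hp: FSVMHyperparams | None = None,
    scheme: str = "centroid-linear",
    sigma: float = 0.05,
    classes: list | None = None,
) -> MulticlassFSVM:
    """One binary FSVM per class; memberships recomputed per binary task."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    cls = list(classes) if classes is not None else list(np.unique(labels))
    if len(cls) < 2:
        raise ValueError("need at least two classes")
    ensemble = MulticlassFSVM(classes=cls)
    for c in cls:
        y = np.where(labels == c, 1.0, -1.0)
        if np.sum(y > 0) < 2:
            warnings.warn(f"class {c!r} has < 2 samples; margin may be degenerate")
        ensemble.models.append(
            train_fsvm(X, y, hp=hp, scheme=scheme, sigma=sigma)
        )
    return ensemble
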