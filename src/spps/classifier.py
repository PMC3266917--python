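"""SVM pair-classifier with sigmoid posterior-probability calibration.

A labeled set of protein pairs is featurized as concatenated
conjoint-triad vectors and fed to a support-vector machine (RBF kernel
by default).  Raw SVM decision values f(x) are mapped to posterior
interaction probabilities with Platt's sigmoid,

    P(interact | f) = 1 / (1 + exp(A*f + B)),

where (A, B) minimize the negative log-likelihood of held-out decision
values under Platt's regularized targets t+ = (N+ + 1)/(N+ + 2) and
t- = 1/(N- + 2).  The calibration data come from an internal 3-fold
split of the training set, not from the training fit itself, to avoid
optimistically steep sigmoids.  With the positive class on the larger
decision values the fitted A is negative (the sigmoid increases in f);
a positive fitted A signals anti-learning and is logged as a warning.

The minimizer is a damped Newton iteration on the two-parameter
objective with backtracking line search — the standard numerically
robust formulation of the likelihood (no explicit exp of large
arguments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import (
    CalibrationError,
    FingerprintMismatchError,
    UnknownProteinError,
    ValidationError,
)
from .features import ResidueClassMap, pair_vector, triad_vector
from .protein_db import ProteinDatabase

logger = logging.getLogger(__name__)

POSITIVE_LABEL = 1  # "interact"
NEGATIVE_LABEL = 0  # "non-interact"

#: Default seed for every stochastic step (recorded in model metadata).
DEFAULT_SEED = 20120126


@dataclass
class PPIDataset:
    """Labeled protein-ID pairs: (id_a, id_b, label) with label 1=interact."""

    pairs: List[Tuple[str, str, int]]

    def __post_init__(self) -> None:
        seen: dict = {}
        for a, b, y in self.pairs:
            if y not in (POSITIVE_LABEL, NEGATIVE_LABEL):
                raise ValidationError(f"label must be 0 or 1, got {y!r}")
            key = frozenset((a, b))
            if key in seen and seen[key] != y:
                raise ValidationError(
                    f"pair ({a}, {b}) appears with conflicting labels"
                )
            seen[key] = y

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.pairs], dtype=int)

    def class_counts(self) -> Tuple[int, int]:
        y = self.labels
        return int((y == POSITIVE_LABEL).sum()), int((y == NEGATIVE_LABEL).sum())

    @classmethod
    def from_tsv(cls, path) -> "PPIDataset":
        """Read a 3-column TSV (id_a, id_b, label) with header."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
        for col in ("id_a", "id_b", "label"):
            if col not in df.columns:
                raise ValidationError(f"pair table lacks column {col!r}")
        return cls(list(df[["id_a", "id_b", "label"]].itertuples(index=False, name=None)))

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.pairs, columns=["id_a", "id_b", "label"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class CalibrationFit:
    """Result of fitting the two-parameter sigmoid."""

    A: float
    B: float
    converged: bool
    iterations: int
    nll: float


def platt_objective(A: float, B: float, decision_values, targets) -> float:
    """Negative log-likelihood of targets under P = 1/(1+exp(A*f+B)).

    Evaluated in the overflow-safe form sum(t*z + log(1+exp(-z))) with
    the two branches chosen by sign(z).
    """
    f = np.asarray(decision_values, dtype=float)
    t = np.asarray(targets, dtype=float)
    z = A * f + B
    pos = z >= 0
    out = np.empty_like(z)
    out[pos] = t[pos] * z[pos] + np.log1p(np.exp(-z[pos]))
    out[~pos] = (t[~pos] - 1.0) * z[~pos] + np.log1p(np.exp(z[~pos]))
    return float(out.sum())


def regularized_targets(labels) -> np.ndarray:
    """Platt's smoothed targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2)."""
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == POSITIVE_LABEL).sum())
    n_neg = int(y.size - n_pos)
    t_pos = (n_pos + 1.0) / (n_pos + 2.0)
    t_neg = 1.0 / (n_neg + 2.0)
    return np.where(y == POSITIVE_LABEL, t_pos, t_neg)


def fit_platt(
    decision_values: Sequence[float],
    labels: Sequence[int],
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CalibrationFit:
    """Fit sigmoid parameters (A, B) by damped Newton minimization.

    Parameters
    ----------
    decision_values
        Raw classifier decision values, ideally out-of-sample.
    labels
        Binary labels (1 = interact); both classes must be present.
    max_iter, tol
        Newton iteration cap and gradient-norm convergence tolerance.

    The iteration starts at A = 0, B = log((N-+1)/(N++1)) (the prior
    solution) and backtracks the step until the objective decreases;
    a tiny ridge keeps the 2x2 Hessian solvable when decision values
    are (near-)constant.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if f.shape != y.shape:
        raise ValidationError("decision values and labels must have equal length")
    n_pos = int((y == POSITIVE_LABEL).sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("calibration requires both classes")
    t = regularized_targets(y)

    sigma = 1e-12  # Hessian ridge
    A = 0.0
    B = float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    fval = platt_objective(A, B, f, t)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = A * f + B
        # p = P(y=1|f); computed branch-wise for stability
        p = np.empty_like(z)
        pos = z >= 0
        ez = np.exp(-z[pos])
        p[pos] = ez / (1.0 + ez)
        ez = np.exp(z[~pos])
        p[~pos] = 1.0 / (1.0 + ez)
        d1 = t - p  # dF/dz
        g_A = float(np.dot(d1, f))
        g_B = float(d1.sum())
        if max(abs(g_A), abs(g_B)) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        h11 = float(np.dot(w, f * f)) + sigma
        h22 = float(w.sum()) + sigma
        h12 = float(np.dot(w, f))
        det = h11 * h22 - h12 * h12
        dA = -(h22 * g_A - h12 * g_B) / det
        dB = -(-h12 * g_A + h11 * g_B) / det
        gd = g_A * dA + g_B * dB
        step = 1.0
        while step >= 1e-10:
            new_A, new_B = A + step * dA, B + step * dB
            new_f = platt_objective(new_A, new_B, f, t)
            if new_f < fval + 1e-4 * step * gd:
                A, B, fval = new_A, new_B, new_f
                break
            step /= 2.0
        else:
            # no descent possible; at a tiny gradient this is numerical
            # stall at the optimum, not failure
            if max(abs(g_A), abs(g_B)) < 1e-6 * max(1.0, y.size):
                converged = True
            else:
                logger.warning("platt line search failed at iteration %d", it)
            break
    return CalibrationFit(A=A, B=B, converged=converged, iterations=it, nll=fval)


def sigmoid_probability(decision_value: float, A: float, B: float) -> float:
    """P(interact | f) = 1/(1 + exp(A*f + B)), overflow-safe."""
    z = A * float(decision_value) + B
    if z >= 0:
        e = np.exp(-z)
        return float(e / (1.0 + e))
    return float(1.0 / (1.0 + np.exp(z)))


@dataclass
class SVMParams:
    """Hyperparameters of the pair classifier.

    With ``tune`` on, (C, gamma) are chosen from the grids by inner
    3-fold accuracy on the training split (ties broken toward the
    first grid entry); otherwise the first grid entries are used as-is.
    """

    C_grid: Tuple[float, ...] = (1.0, 10.0)
    gamma_grid: Tuple[Union[str, float], ...] = ("scale",)
    kernel: str = "rbf"
    tune: bool = True
    calibration_folds: int = 3
    tuning_folds: int = 3
    seed: int = DEFAULT_SEED


@dataclass
class TrainedModel:
    """Fitted SVM decision function plus Platt parameters and the
    featurization settings fingerprint it was trained under."""

    svc: SVC
    platt_A: float
    platt_B: float
    class_map: ResidueClassMap
    fingerprint: str
    params: SVMParams
    calibration: CalibrationFit = None
    chosen_C: float = None
    chosen_gamma: Union[str, float] = None

    def decision_value(self, x: np.ndarray) -> float:
        return float(self.svc.decision_function(x.reshape(1, -1))[0])

    def predict_probability(
        self, seqA: str, seqB: str, symmetrize: bool = True
    ) -> float:
        """Posterior interaction probability of a sequence pair.

        With symmetrization (the default) the probabilities of both
        pair orderings are averaged, making the score independent of
        argument order.
        """
        vA = triad_vector(seqA, self.class_map)
        vB = triad_vector(seqB, self.class_map)
        p_ab = sigmoid_probability(
            self.decision_value(pair_vector(vA, vB).values),
            self.platt_A, self.platt_B,
        )
        if not symmetrize:
            return p_ab
        p_ba = sigmoid_probability(
            self.decision_value(pair_vector(vB, vA).values),
            self.platt_A, self.platt_B,
        )
        return 0.5 * (p_ab + p_ba)

    def check_fingerprint(self, cmap: ResidueClassMap) -> None:
        if cmap.fingerprint() != self.fingerprint:
            raise FingerprintMismatchError(
                "model was trained under a different residue-class table"
            )

    def save(self, path) -> None:
        joblib.dump(
            {
                "svc": self.svc,
                "platt_A": self.platt_A,
                "platt_B": self.platt_B,
                "class_map": {
                    "mapping": self.class_map.mapping,
                    "ambiguity_policy": self.class_map.ambiguity_policy,
                },
                "fingerprint": self.fingerprint,
                "params": self.params,
                "calibration": self.calibration,
                "chosen_C": self.chosen_C,
                "chosen_gamma": self.chosen_gamma,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        cmap = ResidueClassMap(**blob["class_map"])
        if cmap.fingerprint() != blob["fingerprint"]:
            raise FingerprintMismatchError(
                "stored fingerprint does not match the stored residue-class table"
            )
        return cls(
            svc=blob["svc"],
            platt_A=blob["platt_A"],
            platt_B=blob["platt_B"],
            class_map=cmap,
            fingerprint=blob["fingerprint"],
            params=blob["params"],
            calibration=blob["calibration"],
            chosen_C=blob["chosen_C"],
            chosen_gamma=blob["chosen_gamma"],
        )


def _pair_matrix(
    data: PPIDataset, db: ProteinDatabase, cmap: ResidueClassMap
) -> np.ndarray:
    cache: dict = {}

    def vec(pid: str):
        if pid not in cache:
            if pid not in db:
                raise UnknownProteinError(f"pair references unknown protein {pid!r}")
            cache[pid] = triad_vector(db.sequence(pid), cmap)
        return cache[pid]

    return np.vstack(
        [pair_vector(vec(a), vec(b)).values for a, b, _ in data.pairs]
    )


def _select_hyperparams(
    X: np.ndarray, y: np.ndarray, params: SVMParams
) -> Tuple[float, Union[str, float]]:
    grid = [(C, g) for C in params.C_grid for g in params.gamma_grid]
    if not params.tune or len(grid) == 1:
        return grid[0]
    skf = StratifiedKFold(
        n_splits=params.tuning_folds, shuffle=True, random_state=params.seed
    )
    best = None
    for C, gamma in grid:
        correct = 0
        for tr, te in skf.split(X, y):
            svc = SVC(C=C, gamma=gamma, kernel=params.kernel)
            svc.fit(X[tr], y[tr])
            correct += int((svc.predict(X[te]) == y[te]).sum())
        if best is None or correct > best[0]:
            best = (correct, C, gamma)
    return best[1], best[2]


def train_svm(
    data: PPIDataset,
    db: ProteinDatabase,
    params: Optional[SVMParams] = None,
    cmap: Optional[ResidueClassMap] = None,
) -> TrainedModel:
    """Train the pair classifier and calibrate its probabilities.

    Steps: featurize every pair as [vA || vB]; optionally pick (C, gamma)
    by inner-fold accuracy; collect out-of-sample decision values from a
    3-fold split and fit the Platt sigmoid on them; refit the SVM on the
    full training set.  Deterministic given ``params.seed``.
    """
    params = params or SVMParams()
    cmap = cmap or ResidueClassMap.default()
    n_pos, n_neg = data.class_counts()
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("training data must contain both classes")
    n_cal = min(params.calibration_folds, n_pos, n_neg)
    if n_cal < 2:
        raise ValidationError(
            "need at least 2 examples per class for calibration folds"
        )
    X = _pair_matrix(data, db, cmap)
    y = data.labels

    C, gamma = _select_hyperparams(X, y, params)

    # out-of-sample decision values for calibration
    skf = StratifiedKFold(n_splits=n_cal, shuffle=True, random_state=params.seed)
    dec = np.empty(len(y), dtype=float)
    for tr, te in skf.split(X, y):
        svc = SVC(C=C, gamma=gamma, kernel=params.kernel)
        svc.fit(X[tr], y[tr])
        dec[te] = svc.decision_function(X[te])
    calibration = fit_platt(dec, y)
    if calibration.A > 0:
        logger.warning(
            "fitted Platt A = %.3f > 0: decision values anti-correlate "
            "with the positive class", calibration.A,
        )

    svc = SVC(C=C, gamma=gamma, kernel=params.kernel)
    svc.fit(X, y)
    return TrainedModel(
        svc=svc,
        platt_A=calibration.A,
        platt_B=calibration.B,
        class_map=cmap,
        fingerprint=cmap.fingerprint(),
        params=params,
        calibration=calibration,
        chosen_C=C,
        chosen_gamma=gamma,
    )


def predict_probability(
    model: TrainedModel, seqA: str, seqB: str, symmetrize: bool = True
) -> float:
    """Functional alias of :meth:`TrainedModel.predict_probability`."""
    return model.predict_probability(seqA, seqB, symmetrize=symmetrize)


def sample_negative_pairs(
    positives: Sequence[Tuple[str, str]],
    protein_ids: Sequence[str],
    ratio: float = 1.0,
    seed: int = DEFAULT_SEED,
) -> List[Tuple[str, str, int]]:
    """Sample random non-edge pairs as negatives.

    Draws ``round(ratio * len(positives))`` unordered pairs uniformly
    from pairs not present in *positives* (default ratio 1:1).
    """
    rng = np.random.default_rng(seed)
    pos_set = {frozenset(p) for p in positives}
    ids = sorted(protein_ids)
    n_needed = int(round(ratio * len(positives)))
    out: List[Tuple[str, str, int]] = []
    chosen = set()
    max_possible = len(ids) * (len(ids) - 1) // 2 - len(pos_set)
    if n_needed > max_possible:
        raise ValidationError("not enough non-edge pairs to sample negatives")
    while len(out) < n_needed:
        a, b = rng.choice(len(ids), size=2, replace=False)
        key = frozenset((ids[a], ids[b]))
        if key in pos_set or key in chosen:
            continue
        chosen.add(key)
        out.append((ids[a], ids[b], NEGATIVE_LABEL))
    return out
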