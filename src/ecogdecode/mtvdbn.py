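"""Modified time-varying dynamic Bayesian network (MTVDBN) direction decoder.

One linear-Gaussian network per movement direction models the 1 s (T = 10
step) pre-onset feature window. For node m at slice t,

    x[t, m] = a_temporal . x[t-1, parents] + a_spatial . x[t, parents] + eps,

with eps ~ N(0, 1) under per-node/per-slice standardization. Parents are
selected per node by an L1-penalized least-squares problem

    min (1/N) sum_n r_n^2 + lambda (||a_temporal||_1 + ||a_spatial||_1),

solved on the LARS path. L1 screening does not guarantee acyclic
within-slice graphs, so a hill-climbing pass greedily assembles a DAG from
the screened spatial candidates; final coefficients are refit unpenalized on
the surviving parent sets (relaxed-lasso style). Classification scores a
test window under all direction models and returns the argmin of the total
squared residual (the negative log-likelihood up to constants), ties going
to the lowest direction index.

The boundary slice t = 1 has no temporal parents (there is no t = 0 inside
the window); its likelihood term uses spatial parents only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LassoLars
from sklearn.model_selection import StratifiedKFold

DEFAULT_T = 10
DEFAULT_LAMBDA_GRID = (0.001, 0.01, 0.1, 0.3, 1.0, 3.0, 10.0)
_TINY = 1e-12


def _lasso_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Minimize (1/N)||y - Xa||^2 + lam ||a||_1 (LARS path solver)."""
    if lam < 0:
        raise ValueError("penalty coefficient lambda must be non-negative")
    if X.shape[1] == 0:
        return np.zeros(0)
    if lam == 0:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef
    # sklearn objective is (1/2N)||r||^2 + alpha ||a||_1 -> alpha = lam / 2
    model = LassoLars(alpha=lam / 2.0, fit_intercept=False)
    model.fit(X, y)
    return np.asarray(model.coef_, dtype=float)


def learn_node_coefficients(node: int, t: int, windows: np.ndarray,
                            lam: float) -> tuple[np.ndarray, np.ndarray]:
    """L1 parent screening for one node at one slice.

    ``windows`` has shape (N, T, M). Returns full-length coefficient rows
    (temporal over all M features at t-1, zeros-only when t == 0; spatial
    over all M with a structural zero at ``node``); zeros mark absent edges.
    """
    windows = np.asarray(windows, dtype=float)
    N, T, M = windows.shape
    if N < 2:
        raise ValueError("need at least two training windows")
    y = windows[:, t, node]
    spatial_idx = np.array([j for j in range(M) if j != node])
    if t > 0:
        design = np.hstack([windows[:, t - 1, :],
                            windows[:, t, spatial_idx]])
    else:
        design = windows[:, t, spatial_idx]
    coef = _lasso_fit(design, y, lam)
    temporal = np.zeros(M)
    spatial = np.zeros(M)
    if t > 0:
        temporal = coef[:M].copy()
        spatial[spatial_idx] = coef[M:]
    else:
        spatial[spatial_idx] = coef
    return temporal, spatial


def _node_objective(y: np.ndarray, cols: np.ndarray,
                    lam: float) -> tuple[float, np.ndarray]:
    """(1/N) RSS + lam * ||coef||_1 of the unpenalized LS refit."""
    N = y.size
    if cols.shape[1] == 0:
        return float(np.mean(y**2)), np.zeros(0)
    coef, *_ = np.linalg.lstsq(cols, y, rcond=None)
    resid = y - cols @ coef
    return float(np.mean(resid**2) + lam * np.sum(np.abs(coef))), coef


def build_acyclic_structure(t: int, candidates: dict[int, list[int]],
                            windows: np.ndarray, lam: float,
                            temporal_parents: dict[int, np.ndarray]
                            ) -> dict[int, list[int]]:
    """Assemble a within-slice DAG from screened spatial candidates.

    Hill climbing over edge additions, deletions, and reversals: each move
    refits the affected node(s) by least squares (temporal parents fixed)
    and scores the penalized residual; the move with the largest decrease in
    total score is applied, with any move rejected that would close a
    directed cycle in the slice. Reversals resolve the orientation conflicts
    that pure forward addition commits to too early (both endpoints naming
    each other as candidates). Ties break toward the lexicographically
    smallest (child, parent) pair. Terminates at a local optimum, which on
    screened sparse candidate sets is the restricted-DAG optimum in
    practice.
    """
    windows = np.asarray(windows, dtype=float)
    N, T, M = windows.shape

    def design(m: int, spatial: list[int]) -> np.ndarray:
        cols = []
        tp = temporal_parents.get(m)
        if t > 0 and tp is not None and len(tp) > 0:
            cols.append(windows[:, t - 1, list(tp)])
        if spatial:
            cols.append(windows[:, t, sorted(spatial)])
        if not cols:
            return np.empty((N, 0))
        return np.hstack(cols)

    _obj_cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def node_obj(m: int, spatial: list[int]) -> float:
        key = (m, tuple(sorted(spatial)))
        if key not in _obj_cache:
            _obj_cache[key] = _node_objective(windows[:, t, m],
                                              design(m, spatial), lam)[0]
        return _obj_cache[key]

    def climb(init: dict[int, list[int]]):
        """Greedy add/delete/reverse moves from a given state to a local
        optimum; returns (parents, per-node objectives)."""
        parents = {m: list(ps) for m, ps in init.items()}
        graph = nx.DiGraph()
        graph.add_nodes_from(range(M))
        graph.add_edges_from((p, m) for m, ps in parents.items() for p in ps)
        obj = {m: node_obj(m, parents[m]) for m in range(M)}
        while True:
            best_delta, best_move = _TINY, None
            for m in sorted(candidates):
                for p in sorted(candidates[m]):
                    if p == m:
                        continue
                    if p in parents[m]:
                        # deletion move
                        new_obj = node_obj(
                            m, [q for q in parents[m] if q != p])
                        delta = obj[m] - new_obj
                        if delta > best_delta:
                            best_delta = delta
                            best_move = ("del", m, p, {m: new_obj})
                        # reversal p->m => m->p (if m is p's candidate)
                        if m in candidates.get(p, ()):
                            graph.remove_edge(p, m)
                            acyclic = not nx.has_path(graph, p, m)
                            graph.add_edge(p, m)
                            if acyclic:
                                new_m = node_obj(
                                    m, [q for q in parents[m] if q != p])
                                new_p = node_obj(p, parents[p] + [m])
                                delta = (obj[m] - new_m) + (obj[p] - new_p)
                                if delta > best_delta:
                                    best_delta = delta
                                    best_move = ("rev", m, p,
                                                 {m: new_m, p: new_p})
                    else:
                        # addition move, must keep the slice acyclic
                        if nx.has_path(graph, m, p):
                            continue
                        new_obj = node_obj(m, parents[m] + [p])
                        delta = obj[m] - new_obj
                        if delta > best_delta:
                            best_delta = delta
                            best_move = ("add", m, p, {m: new_obj})
            if best_move is None:
                return parents, obj
            kind, m, p, new_objs = best_move
            if kind == "add":
                parents[m].append(p)
                graph.add_edge(p, m)
            elif kind == "del":
                parents[m].remove(p)
                graph.remove_edge(p, m)
            else:
                parents[m].remove(p)
                graph.remove_edge(p, m)
                parents[p].append(m)
                graph.add_edge(m, p)
            obj.update(new_objs)

    parents, obj = climb({m: [] for m in range(M)})
    # single-edge-reversal perturbations: re-climb from each state with one
    # retained edge flipped, escaping orientation-conflict local optima.
    # The refinement is quadratic in the edge count, so it is reserved for
    # sparse slices (where it provably closes the gap to exhaustive search);
    # dense slices rely on the add/delete/reverse moves above.
    n_edges = sum(len(ps) for ps in parents.values())
    improved = n_edges <= 16
    while improved:
        improved = False
        total = sum(obj.values())
        for m in sorted(parents):
            for p in sorted(parents[m]):
                if m not in candidates.get(p, ()):
                    continue
                init = {q: [r for r in ps if (q, r) != (m, p)]
                        for q, ps in parents.items()}
                g = nx.DiGraph()
                g.add_nodes_from(range(M))
                g.add_edges_from((r, q) for q, ps in init.items()
                                 for r in ps)
                if nx.has_path(g, p, m):
                    continue
                init[p] = init[p] + [m]
                cand_parents, cand_obj = climb(init)
                if sum(cand_obj.values()) < total - _TINY:
                    parents, obj = cand_parents, cand_obj
                    improved = True
                    break
            if improved:
                break
    return {m: sorted(ps) for m, ps in parents.items()}


def _greedy_subset(y: np.ndarray, candidates: np.ndarray,
                   columns: np.ndarray, lam: float) -> list[int]:
    """Greedy add/delete subset selection on one node's candidate parents,
    scoring the penalized refit objective (1/N) RSS + lam ||coef||_1.

    L1 screening keeps every feature the penalized path touches; weak
    spurious candidates whose refit coefficient pays more penalty than the
    residual it removes are pruned here by the same objective the screening
    minimizes.
    """
    selected: list[int] = []
    cache: dict[tuple[int, ...], float] = {}

    def objective(subset: list[int]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            cols = columns[:, list(key)] if key else np.empty((y.size, 0))
            cache[key] = _node_objective(y, cols, lam)[0]
        return cache[key]

    current = objective([])
    while True:
        best_delta, best_move = _TINY, None
        for i, c in enumerate(candidates):
            trial = ([s for s in selected if s != c] if c in selected
                     else selected + [int(c)])
            new_obj = objective(trial)
            delta = current - new_obj
            if delta > best_delta:
                best_delta, best_move = delta, (int(c), new_obj)
        if best_move is None:
            break
        c, current = best_move
        if c in selected:
            selected.remove(c)
        else:
            selected.append(c)
    return sorted(selected)


@dataclass
class MtvdbnModel:
    """Fitted per-direction network: parent sets and coefficients per slice."""

    direction: int
    T: int
    M: int
    lam: float
    temporal_parents: list[dict[int, list[int]]] = field(default_factory=list)
    temporal_coefs: list[dict[int, np.ndarray]] = field(default_factory=list)
    spatial_parents: list[dict[int, list[int]]] = field(default_factory=list)
    spatial_coefs: list[dict[int, np.ndarray]] = field(default_factory=list)

    def n_edges(self) -> int:
        return sum(len(ps) for sl in (self.temporal_parents,
                                      self.spatial_parents)
                   for d in sl for ps in d.values())


def empty_model(direction: int, T: int, M: int, lam: float) -> MtvdbnModel:
    """A parent-free model; every window scores as its own sum of squares."""
    model = MtvdbnModel(direction=direction, T=T, M=M, lam=lam)
    for _ in range(T):
        model.temporal_parents.append({m: [] for m in range(M)})
        model.temporal_coefs.append({m: np.zeros(0) for m in range(M)})
        model.spatial_parents.append({m: [] for m in range(M)})
        model.spatial_coefs.append({m: np.zeros(0) for m in range(M)})
    return model


def fit_direction_model(windows: np.ndarray, direction: int, lam: float,
                        T: int | None = None) -> MtvdbnModel:
    """Fit one direction's MTVDBN on standardized pre-onset windows.

    Per node and slice: L1 screening selects candidate parents, hill
    climbing repairs within-slice acyclicity, and the final coefficients are
    refit by unpenalized least squares on the surviving parent sets.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3:
        raise ValueError("windows must be (n_trials, T, M)")
    N, T_w, M = windows.shape
    if T is None:
        T = T_w
    if N < 2:
        raise ValueError("need at least two trials per direction")
    model = MtvdbnModel(direction=direction, T=T, M=M, lam=lam)
    for t in range(T):
        tpar_sets: dict[int, np.ndarray] = {}
        cand: dict[int, list[int]] = {}
        for m in range(M):
            temporal, spatial = learn_node_coefficients(m, t, windows, lam)
            tcand = np.flatnonzero(np.abs(temporal) > _TINY)
            if t > 0 and tcand.size:
                tcand = np.asarray(_greedy_subset(
                    windows[:, t, m], tcand, windows[:, t - 1, :], lam),
                    dtype=int)
            tpar_sets[m] = tcand
            cand[m] = list(np.flatnonzero(np.abs(spatial) > _TINY))
        spar = build_acyclic_structure(t, cand, windows, lam, tpar_sets)
        tp_d, tc_d, sp_d, sc_d = {}, {}, {}, {}
        for m in range(M):
            tp = list(tpar_sets[m]) if t > 0 else []
            sp = spar[m]
            cols = []
            if tp:
                cols.append(windows[:, t - 1, tp])
            if sp:
                cols.append(windows[:, t, sp])
            if cols:
                X = np.hstack(cols)
                coef, *_ = np.linalg.lstsq(X, windows[:, t, m], rcond=None)
            else:
                coef = np.zeros(0)
            tp_d[m], sp_d[m] = tp, sp
            tc_d[m] = coef[:len(tp)].copy()
            sc_d[m] = coef[len(tp):].copy()
        model.temporal_parents.append(tp_d)
        model.temporal_coefs.append(tc_d)
        model.spatial_parents.append(sp_d)
        model.spatial_coefs.append(sc_d)
    return model


def score_sequence(model: MtvdbnModel, window: np.ndarray) -> float:
    """Negative log-likelihood score (total squared residual) of a window."""
    window = np.asarray(window, dtype=float)
    if window.shape != (model.T, model.M):
        raise ValueError(f"window must be ({model.T}, {model.M})")
    total = 0.0
    for t in range(model.T):
        for m in range(model.M):
            pred = 0.0
            tp = model.temporal_parents[t][m]
            if t > 0 and tp:
                pred += model.temporal_coefs[t][m] @ window[t - 1, tp]
            sp = model.spatial_parents[t][m]
            if sp:
                pred += model.spatial_coefs[t][m] @ window[t, sp]
            total += (window[t, m] - pred) ** 2
    return float(total)


def classify_direction(models: list[MtvdbnModel],
                       window: np.ndarray) -> int:
    """Argmin of the per-direction scores; ties go to the lowest index."""
    if not models or any(m is None for m in models):
        raise ValueError("all direction models must be trained")
    scores = [score_sequence(m, window) for m in models]
    return int(np.argmin(scores))


def angular_error(predicted: int, true: int, n_targets: int = 8) -> float:
    """Absolute angular error in degrees between two target indices."""
    spacing = 360.0 / n_targets
    delta = abs(spacing * (int(predicted) - int(true))) % 360.0
    return float(min(delta, 360.0 - delta))


class MtvdbnDirectionClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style 8-direction classifier built on per-direction MTVDBNs.

    Parameters
    ----------
    lam : float or "cv"
        Penalty coefficient of the L1 screening; "cv" selects it from
        ``lambda_grid`` by trial-wise cross-validated accuracy with a
        one-standard-error tie rule (largest lambda within one SE of the
        best, favoring sparsity).
    T : int
        Window length in 100 ms steps (default 10, i.e. 1 s).

    Windows may be passed as (n, T, M) arrays or flattened (n, T*M)
    matrices. Features are standardized per node and slice on the training
    trials (jointly across directions), supporting the unit-variance noise
    assumption; the same scaler standardizes test windows.
    """

    def __init__(self, lam="cv", lambda_grid=DEFAULT_LAMBDA_GRID,
                 T: int = DEFAULT_T, cv: int = 3, one_se: bool = True,
                 random_state: int = 0):
        self.lam = lam
        self.lambda_grid = lambda_grid
        self.T = T
        self.cv = cv
        self.one_se = one_se
        self.random_state = random_state

    def _as_windows(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] % self.T:
                raise ValueError("flattened windows not divisible by T")
            X = X.reshape(X.shape[0], self.T, -1)
        if X.ndim != 3 or X.shape[1] != self.T:
            raise ValueError(f"expected (n, {self.T}, M) windows")
        return X

    def _standardize(self, W: np.ndarray) -> np.ndarray:
        return (W - self.mean_) / self.std_

    def _fit_models(self, W, y, lam):
        models = []
        for d in self.classes_:
            Wd = W[y == d]
            if Wd.shape[0] < 2:
                import warnings
                warnings.warn(f"direction {d}: fewer than two trials; "
                              "falling back to an empty (parent-free) model")
                models.append(empty_model(int(d), W.shape[1], W.shape[2],
                                          lam))
            else:
                models.append(fit_direction_model(Wd, int(d), lam))
        return models

    def _predict_std(self, models, Wstd):
        scores = np.array([[score_sequence(m, w) for m in models]
                           for w in Wstd])
        return self.classes_[np.argmin(scores, axis=1)], scores

    def fit(self, X, y):
        W = self._as_windows(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.mean_ = W.mean(axis=0)
        std = W.std(axis=0)
        self.std_ = np.where(std > 0, std, 1.0)
        Wstd = self._standardize(W)
        if self.lam == "cv":
            self.lam_ = select_lambda(
                Wstd, y, self.lambda_grid, cv=self.cv, one_se=self.one_se,
                random_state=self.random_state, prestandardized=True)
        else:
            self.lam_ = float(self.lam)
        self.models_ = self._fit_models(Wstd, y, self.lam_)
        return self

    def predict(self, X):
        Wstd = self._standardize(self._as_windows(X))
        pred, _ = self._predict_std(self.models_, Wstd)
        return pred

    def decision_scores(self, X) -> np.ndarray:
        """Per-direction negative log-likelihood scores (n, n_classes)."""
        Wstd = self._standardize(self._as_windows(X))
        _, scores = self._predict_std(self.models_, Wstd)
        return scores


def select_lambda(windows: np.ndarray, y: np.ndarray,
                  lambda_grid=DEFAULT_LAMBDA_GRID, cv: int = 3,
                  one_se: bool = True, random_state: int = 0,
                  prestandardized: bool = False) -> float:
    """Pick the penalty by trial-wise cross-validated accuracy.

    With the one-SE rule the sparsest (largest) lambda whose mean accuracy
    is within one standard error of the best is returned; without it, the
    best-accuracy lambda (ties toward larger lambda).
    """
    grid = sorted(set(float(l) for l in lambda_grid))
    if not grid:
        raise ValueError("lambda grid is empty")
    if len(grid) == 1:
        return grid[0]
    windows = np.asarray(windows, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=cv, shuffle=True,
                          random_state=random_state)
    accs = {lam: [] for lam in grid}
    for tr, te in skf.split(windows[:, 0, 0], y):
        Wtr, Wte = windows[tr], windows[te]
        if not prestandardized:
            mean = Wtr.mean(axis=0)
            std = np.where(Wtr.std(axis=0) > 0, Wtr.std(axis=0), 1.0)
            Wtr, Wte = (Wtr - mean) / std, (Wte - mean) / std
        for lam in grid:
            models = [
                fit_direction_model(Wtr[y[tr] == d], int(d), lam)
                if np.sum(y[tr] == d) >= 2
                else empty_model(int(d), Wtr.shape[1], Wtr.shape[2], lam)
                for d in classes]
            pred = np.array([classes[int(np.argmin(
                [score_sequence(m, w) for m in models]))] for w in Wte])
            accs[lam].append(float(np.mean(pred == y[te])))
    means = {lam: float(np.mean(a)) for lam, a in accs.items()}
    best = max(grid, key=lambda l: (means[l], l))
    if not one_se:
        return best
    se = float(np.std(accs[best], ddof=1) / np.sqrt(len(accs[best]))) \
        if len(accs[best]) > 1 else 0.0
    eligible = [l for l in grid if means[l] >= means[best] - se]
    return max(eligible)
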