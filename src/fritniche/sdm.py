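"""Ensemble species-distribution modelling.

The modelling object is :class:`EnsembleSDM`: built from an environmental
presence/pseudo-absence table, its :meth:`~EnsembleSDM.fit` evaluates each
member algorithm over repeated stratified train/test splits (AUC, TSS and
kappa per run), keeps members whose mean test AUC exceeds the ROC cutoff
(0.9 by default), refits them on the full table and combines them as an
AUC-weighted mean of member probabilities. The returned
:class:`EnsembleSDMResults` carries the score table, member weights, a
``summary()``, raster projection, response curves, suitable ranges,
variable importance and habitat grading.

Mandatory members, implemented from their definitions: the surface range
envelope (a per-variable quantile box) and an IRLS-fitted logistic model on
standardized variables (with optional quadratic terms, the default for
response-curve work). Further learners (rf, cta, ann, fda, gbm) plug in
through the same fit/predict contract via scikit-learn.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import auc_score, best_tss_threshold, confusion_metrics
from .occurrences import PSEUDO_ABSENCE, OccurrenceSet, env_columns
from .raster import RasterGrid, RasterStack, cell_area_km2

logger = logging.getLogger(__name__)

GRADE_NAMES = {0: "not", 1: "low", 2: "moderate", 3: "high"}
GRADE_BINS = (0.25, 0.5, 0.75)


# ---------------------------------------------------------------------------
# Surface range envelope

@dataclass
class SREModel:
    """Per-variable [q, 1-q] empirical quantile envelope; predicts 1 iff
    every variable lies inside its interval (inclusive)."""

    bounds: dict[str, tuple[float, float]]
    q: float

    @property
    def variables(self) -> list[str]:
        return list(self.bounds)

    def predict(self, env: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.bounds if v not in env.columns]
        if missing:
            raise ValueError(f"missing variables {missing}")
        ok = np.ones(len(env), dtype=bool)
        for var, (lo, hi) in self.bounds.items():
            x = env[var].to_numpy(dtype=float)
            ok &= (x >= lo) & (x <= hi)
        return ok.astype(float)


def fit_sre(presence_env: pd.DataFrame, q: float = 0.025,
            variables: list[str] | None = None) -> SREModel:
    """Quantile envelope over presence rows (q=0 gives the min/max box)."""
    if not 0 <= q < 0.5:
        raise ValueError("q must lie in [0, 0.5)")
    if len(presence_env) < 5:
        raise ValueError("need at least 5 presence rows")
    if variables is None:
        variables = env_columns(presence_env) or list(presence_env.columns)
    bounds = {}
    for var in variables:
        x = presence_env[var].to_numpy(dtype=float)
        lo, hi = np.quantile(x, [q, 1 - q])
        bounds[var] = (float(lo), float(hi))
    return SREModel(bounds, q)


def predict_sre(model: SREModel, env: pd.DataFrame) -> np.ndarray:
    return model.predict(env)


def sample_pseudo_absences(
    stack: RasterStack,
    sre: SREModel,
    n: int,
    seed: int = 0,
    species: str = "background",
    exclude: OccurrenceSet | None = None,
) -> OccurrenceSet:
    """``n`` distinct cells sampled uniformly among SRE-unsuitable,
    non-nodata cells (cells holding an excluded record are ineligible);
    records take cell-centre coordinates, kind=pseudo_absence."""
    table, rows, cols = stack.table()
    env = pd.DataFrame(table, columns=stack.names)
    unsuitable = sre.predict(env) == 0
    eligible = np.nonzero(unsuitable)[0]
    if exclude is not None and len(exclude):
        tmpl = stack.grid_template()
        er, ec, inside = tmpl.index_of(exclude.frame["lon"].to_numpy(),
                                       exclude.frame["lat"].to_numpy())
        used = set(zip(er[inside].tolist(), ec[inside].tolist()))
        eligible = np.array([i for i in eligible
                             if (rows[i], cols[i]) not in used], dtype=int)
    if eligible.size < n:
        raise ValueError(
            f"only {eligible.size} SRE-unsuitable cells available, need {n} "
            f"({n - eligible.size} short)")
    rng = np.random.default_rng(seed)
    picks = rng.choice(eligible, size=n, replace=False)
    tmpl = stack.grid_template()
    lon, lat = tmpl.cell_center(rows[picks], cols[picks])
    return OccurrenceSet(pd.DataFrame({
        "species": species, "lon": lon, "lat": lat, "kind": PSEUDO_ABSENCE}))


# ---------------------------------------------------------------------------
# Logistic member (IRLS)

@dataclass
class LogisticIRLS:
    """Logistic-linear model fitted by iteratively reweighted least squares
    on standardized variables; ``degree=2`` appends squared terms so the
    per-variable response can peak at an interior optimum."""

    degree: int = 1
    max_iter: int = 500
    tol: float = 1e-8
    variables: list[str] = field(default_factory=list)
    coef: np.ndarray | None = None
    converged: bool = False
    separation_flag: bool = False
    n_iter: int = 0
    _mean: np.ndarray | None = None
    _sd: np.ndarray | None = None

    def _design(self, env: pd.DataFrame) -> np.ndarray:
        x = env[self.variables].to_numpy(dtype=float)
        z = (x - self._mean) / self._sd
        parts = [np.ones((len(z), 1)), z]
        if self.degree >= 2:
            parts.append(z ** 2)
        return np.hstack(parts)

    def fit(self, env: pd.DataFrame, y) -> "LogisticIRLS":
        y = np.asarray(y, dtype=float)
        if np.unique(y).size < 2:
            raise ValueError("both classes required to fit the logistic member")
        if not self.variables:
            self.variables = env_columns(env) or list(env.columns)
        x = env[self.variables].to_numpy(dtype=float)
        self._mean = x.mean(axis=0)
        sd = x.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        X = self._design(env)
        beta = np.zeros(X.shape[1])
        for it in range(1, self.max_iter + 1):
            eta = np.clip(X @ beta, -30, 30)
            mu = 1 / (1 + np.exp(-eta))
            w = np.maximum(mu * (1 - mu), 1e-10)
            z = eta + (y - mu) / w
            xtw = X.T * w
            new = np.linalg.solve(xtw @ X + 1e-9 * np.eye(X.shape[1]), xtw @ z)
            step = np.max(np.abs(new - beta))
            beta = new
            if step < self.tol:
                self.converged = True
                break
        self.n_iter = it
        self.coef = beta
        if not self.converged or np.max(np.abs(beta)) > 25:
            self.separation_flag = True
            logger.info("logistic fit hit the iteration cap or diverging "
                        "coefficients (possible perfect separation)")
        return self

    def predict(self, env: pd.DataFrame) -> np.ndarray:
        if self.coef is None:
            raise ValueError("model is not fitted")
        eta = np.clip(self._design(env) @ self.coef, -30, 30)
        return 1 / (1 + np.exp(-eta))


def fit_logistic(env: pd.DataFrame, max_iter: int = 500, degree: int = 1,
                 variables: list[str] | None = None) -> LogisticIRLS:
    """Fit the IRLS logistic member on an extracted table with a ``label``
    column."""
    model = LogisticIRLS(degree=degree, max_iter=max_iter,
                         variables=variables or [])
    return model.fit(env, env["label"].to_numpy())


# ---------------------------------------------------------------------------
# Member registry

class _SREMember:
    def __init__(self, q: float = 0.025):
        self.q = q
        self.model: SREModel | None = None

    def fit(self, env: pd.DataFrame, y):
        presence = env[np.asarray(y) == 1]
        self.model = fit_sre(presence, q=self.q,
                             variables=env_columns(env) or list(env.columns))
        return self

    def predict(self, env: pd.DataFrame) -> np.ndarray:
        return self.model.predict(env)


class _GLMMember:
    def __init__(self, degree: int = 2, max_iter: int = 500):
        self.degree = degree
        self.max_iter = max_iter
        self.model: LogisticIRLS | None = None

    def fit(self, env: pd.DataFrame, y):
        self.model = LogisticIRLS(degree=self.degree, max_iter=self.max_iter)
        self.model.fit(env, y)
        return self

    def predict(self, env: pd.DataFrame) -> np.ndarray:
        return self.model.predict(env)


class _SKLearnMember:
    """Adapter for pluggable scikit-learn learners."""

    def __init__(self, factory):
        self.factory = factory
        self.est = None
        self.variables: list[str] = []

    def fit(self, env: pd.DataFrame, y):
        self.variables = env_columns(env) or list(env.columns)
        self.est = self.factory()
        self.est.fit(env[self.variables].to_numpy(dtype=float), np.asarray(y))
        return self

    def predict(self, env: pd.DataFrame) -> np.ndarray:
        X = env[self.variables].to_numpy(dtype=float)
        return self.est.predict_proba(X)[:, 1]


def _sklearn_factories():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.tree import DecisionTreeClassifier

    return {
        "rf": lambda: RandomForestClassifier(n_estimators=200, random_state=0),
        "cta": lambda: DecisionTreeClassifier(max_depth=6, random_state=0),
        "gbm": lambda: GradientBoostingClassifier(random_state=0),
        "ann": lambda: MLPClassifier(hidden_layer_sizes=(16,), max_iter=500,
                                     random_state=0),
        "fda": lambda: LinearDiscriminantAnalysis(),
    }


def make_member(name: str, sre_q: float = 0.025, max_iter: int = 500):
    if name == "sre":
        return _SREMember(q=sre_q)
    if name == "glm":
        return _GLMMember(max_iter=max_iter)
    factories = _sklearn_factories()
    if name in factories:
        return _SKLearnMember(factories[name])
    raise ValueError(f"unknown algorithm {name!r}; known: sre, glm, "
                     f"{', '.join(sorted(factories))}")


# ---------------------------------------------------------------------------
# Cross-validation

def _stratified_split(y: np.ndarray, train_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        k = int(round(train_frac * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def cross_validate(
    env: pd.DataFrame,
    algorithms=("sre", "glm"),
    split: float = 0.8,
    n_runs: int = 15,
    seed: int = 0,
    sre_q: float = 0.025,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Per-run AUC/TSS/kappa over stratified random train/test splits.

    Each run uses a fresh split; TSS and kappa are evaluated at the lowest
    TSS-maximizing threshold on the test scores. Run seeds derive from the
    master seed.
    """
    if not 0 < split < 1:
        raise ValueError("split must lie in (0, 1)")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    y = env["label"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("both classes required")
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(n_runs):
        for _attempt in range(20):
            tr, te = _stratified_split(y, split, rng)
            if np.unique(y[te]).size == 2 and np.unique(y[tr]).size == 2:
                break
            logger.info("run %d: degenerate split, resampling", run)
        train, test = env.iloc[tr], env.iloc[te]
        for alg in algorithms:
            member = make_member(alg, sre_q=sre_q, max_iter=max_iter)
            member.fit(train, y[tr])
            scores = member.predict(test)
            auc = auc_score(scores, y[te])
            thr = best_tss_threshold(scores, y[te])
            cm = confusion_metrics(scores, y[te], thr)
            rows.append({"algorithm": alg, "run": run, "split": split,
                         "auc": auc, "tss": cm.tss, "kappa": cm.kappa,
                         "threshold": thr})
    return pd.DataFrame(rows)


def evaluate_bootstrap(
    env: pd.DataFrame,
    algorithms=("sre", "glm"),
    n_boot: int = 50,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Optional bootstrap evaluation: fit on a resampled-with-replacement
    training set, score on the out-of-bag rows; returns per-replicate
    scores from which confidence intervals can be read."""
    y = env["label"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_boot):
        for _attempt in range(50):
            idx = rng.integers(0, len(env), size=len(env))
            oob = np.setdiff1d(np.arange(len(env)), idx)
            if oob.size and np.unique(y[idx]).size == 2 and np.unique(y[oob]).size == 2:
                break
        train, test = env.iloc[idx], env.iloc[oob]
        for alg in algorithms:
            member = make_member(alg, **kwargs)
            member.fit(train, y[idx])
            scores = member.predict(test)
            auc = auc_score(scores, y[oob])
            thr = best_tss_threshold(scores, y[oob])
            cm = confusion_metrics(scores, y[oob], thr)
            rows.append({"algorithm": alg, "replicate": b, "auc": auc,
                         "tss": cm.tss, "kappa": cm.kappa, "threshold": thr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ensemble

@dataclass
class Ensemble:
    """AUC-weighted convex combination of fitted member predictors."""

    members: dict[str, object]
    weights: dict[str, float]
    member_aucs: dict[str, float]
    auc_cutoff: float

    def predict(self, env: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(env))
        for name, member in self.members.items():
            out += self.weights[name] * np.asarray(member.predict(env), dtype=float)
        return out


def build_ensemble(members: dict[str, object], member_aucs: dict[str, float],
                   auc_cutoff: float = 0.9) -> Ensemble:
    """Keep members with AUC > cutoff; weights proportional to AUC."""
    included = {n: m for n, m in members.items() if member_aucs[n] > auc_cutoff}
    if not included:
        raise ValueError(
            f"no member exceeds the AUC cutoff {auc_cutoff}; best is "
            f"{max(member_aucs.values()):.3f} — consider relaxing the cutoff")
    total = sum(member_aucs[n] for n in included)
    weights = {n: member_aucs[n] / total for n in included}
    return Ensemble(included, weights, {n: member_aucs[n] for n in included},
                    auc_cutoff)


def predict_raster(ensemble, stack: RasterStack,
                   variables: list[str] | None = None) -> RasterGrid:
    """Cellwise ensemble probability over the stack; nodata propagates."""
    if variables is None:
        variables = stack.names
    missing = [v for v in variables if v not in stack.names]
    if missing:
        raise ValueError(f"stack is missing layers {missing}")
    table, rows, cols = stack.table()
    env = pd.DataFrame(table, columns=stack.names)
    probs = ensemble.predict(env)
    out = np.full(stack.shape, np.nan)
    out[rows, cols] = probs
    return stack.grid_template().like(out, name="suitability")


# ---------------------------------------------------------------------------
# Response curves, ranges, grades, areas, importance

@dataclass
class ResponseCurve:
    variable: str
    grid: np.ndarray
    response: np.ndarray


@dataclass
class SuitableRange:
    """Threshold interval around the response-curve maximum (Table-1 style:
    suitable range, optimum, maximum probability of existence)."""

    variable: str
    lo: float
    hi: float
    optimum: float
    max_probability: float
    threshold: float

    @property
    def empty(self) -> bool:
        return not (np.isfinite(self.lo) and np.isfinite(self.hi))


def response_curve(ensemble, env: pd.DataFrame, variable: str,
                   n_grid: int = 101) -> ResponseCurve:
    """Sweep ``variable`` over its observed range with every other variable
    fixed at its presence-set mean."""
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    variables = env_columns(env)
    if variable not in variables:
        raise ValueError(f"unknown variable {variable!r}")
    presence = env[env["label"] == 1] if "label" in env.columns else env
    grid = np.linspace(env[variable].min(), env[variable].max(), n_grid)
    probe = pd.DataFrame({v: np.full(n_grid, presence[v].mean()) for v in variables})
    probe[variable] = grid
    return ResponseCurve(variable, grid, np.asarray(ensemble.predict(probe), dtype=float))


def suitable_range(curve: ResponseCurve, threshold: float = 0.5) -> SuitableRange:
    """Outermost threshold crossings around the curve's global maximum,
    linearly interpolated between grid points."""
    g, r = curve.grid, curve.response
    imax = int(np.argmax(r))
    optimum = float(g[imax])
    peak = float(r[imax])
    if peak < threshold:
        return SuitableRange(curve.variable, float("nan"), float("nan"),
                             optimum, peak, threshold)
    i = imax
    while i > 0 and r[i - 1] >= threshold:
        i -= 1
    if i == 0:
        lo = float(g[0])
    else:
        lo = float(g[i - 1] + (g[i] - g[i - 1]) * (threshold - r[i - 1]) / (r[i] - r[i - 1]))
    j = imax
    while j < len(g) - 1 and r[j + 1] >= threshold:
        j += 1
    if j == len(g) - 1:
        hi = float(g[-1])
    else:
        hi = float(g[j] + (g[j + 1] - g[j]) * (r[j] - threshold) / (r[j] - r[j + 1]))
    return SuitableRange(curve.variable, lo, hi, optimum, peak, threshold)


def classify_habitat(suitability: RasterGrid) -> RasterGrid:
    """Grades: 0 not [0,0.25), 1 low [0.25,0.5), 2 moderate [0.5,0.75),
    3 high [0.75,1]."""
    vals = suitability.values
    finite = np.isfinite(vals)
    if finite.any() and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    grades = np.full(vals.shape, np.nan)
    grades[finite] = np.digitize(vals[finite], GRADE_BINS)
    return suitability.like(grades, name="habitat_grades")


def area_stats(grades: RasterGrid, domain_mask: RasterGrid | None = None) -> pd.DataFrame:
    """Per-grade area (km^2, spherical cell areas) and percent of the
    domain (default: all graded cells)."""
    areas = cell_area_km2(grades)
    if domain_mask is not None:
        if not grades.aligned_with(domain_mask):
            raise ValueError("grades and domain mask are not aligned")
        domain = np.isfinite(domain_mask.values) & (domain_mask.values != 0)
    else:
        domain = np.isfinite(grades.values)
    total = float(areas[domain].sum())
    rows = []
    for code, name in GRADE_NAMES.items():
        sel = domain & (grades.values == code)
        km2 = float(areas[sel].sum())
        rows.append({"grade": name, "code": code, "km2": km2,
                     "percent": 100 * km2 / total if total > 0 else 0.0})
    df = pd.DataFrame(rows)
    df.attrs["domain_km2"] = total
    return df


def variable_importance(
    ensemble,
    env: pd.DataFrame,
    mode: str = "permutation",
    n_perm: int = 5,
    seed: int = 0,
    algorithms: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Percent importance per variable.

    ``permutation``: 1 - corr(prediction, prediction with the variable
    permuted), averaged over ``n_perm`` shuffles, normalized to 100%.
    ``jackknife``: AUC drop on a held-out split when the variable is
    excluded from refit members, normalized to 100%.
    """
    variables = env_columns(env)
    raw = {}
    if mode == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        base = np.asarray(ensemble.predict(env), dtype=float)
        base_sd = base.std()
        for var in variables:
            drops = []
            for _ in range(n_perm):
                shuffled = env.copy()
                shuffled[var] = rng.permutation(shuffled[var].to_numpy())
                pred = np.asarray(ensemble.predict(shuffled), dtype=float)
                if base_sd == 0 or pred.std() == 0:
                    corr = 1.0 if np.allclose(pred, base) else 0.0
                else:
                    corr = float(np.corrcoef(base, pred)[0, 1])
                drops.append(1 - corr)
            raw[var] = float(np.mean(drops))
    elif mode == "jackknife":
        y = env["label"].to_numpy()
        rng = np.random.default_rng(seed)
        tr, te = _stratified_split(y, 0.8, rng)
        train, test = env.iloc[tr], env.iloc[te]
        full_auc = {}
        for name in ensemble.members:
            m = make_member(name)
            m.fit(train, y[tr])
            full_auc[name] = auc_score(m.predict(test), y[te])
        for var in variables:
            reduced = env.drop(columns=[var])
            drops = []
            for name in ensemble.members:
                m = make_member(name)
                m.fit(reduced.iloc[tr], y[tr])
                drops.append(full_auc[name] - auc_score(m.predict(reduced.iloc[te]), y[te]))
            raw[var] = max(0.0, float(np.mean(drops)))
    else:
        raise ValueError("mode must be 'permutation' or 'jackknife'")
    total = sum(raw.values())
    if total <= 0:
        warnings.warn("zero total importance; reporting uniform percentages")
        pct = {v: 100.0 / len(variables) for v in variables}
    else:
        pct = {v: 100.0 * raw[v] / total for v in variables}
    return pd.DataFrame({"variable": variables,
                         "importance_pct": [pct[v] for v in variables],
                         "raw": [raw[v] for v in variables]})


# ---------------------------------------------------------------------------
# Model / Results

class EnsembleSDM:
    """Ensemble SDM over an extracted environmental table.

    Parameters
    ----------
    env : DataFrame
        Extracted table with variable columns and a ``label`` column
        (1 presence, 0 pseudo-absence).
    algorithms : sequence of str
        Member roster (default the two mandatory members, ``sre`` and
        ``glm``).
    split : float
        Training fraction per evaluation run (0.85, 0.80 and 0.75 mirror
        the conventional splits).
    n_runs : int
        Evaluation runs per algorithm (default 15).
    auc_cutoff : float
        Members with mean test AUC at or below this are excluded (0.9).
    """

    def __init__(self, env: pd.DataFrame, algorithms=("sre", "glm"),
                 split: float = 0.8, n_runs: int = 15, auc_cutoff: float = 0.9,
                 seed: int = 0, sre_q: float = 0.025, max_iter: int = 500):
        if "label" not in env.columns:
            raise ValueError("environmental table needs a 'label' column")
        self.env = env.reset_index(drop=True)
        self.algorithms = tuple(algorithms)
        self.split = split
        self.n_runs = n_runs
        self.auc_cutoff = auc_cutoff
        self.seed = seed
        self.sre_q = sre_q
        self.max_iter = max_iter

    @classmethod
    def from_occurrences(cls, stack: RasterStack, occ: OccurrenceSet, **kwargs):
        from .occurrences import extract_env

        return cls(extract_env(stack, occ), **kwargs)

    def fit(self) -> "EnsembleSDMResults":
        scores = cross_validate(self.env, self.algorithms, split=self.split,
                                n_runs=self.n_runs, seed=self.seed,
                                sre_q=self.sre_q, max_iter=self.max_iter)
        mean_auc = scores.groupby("algorithm")["auc"].mean().to_dict()
        members = {}
        y = self.env["label"].to_numpy()
        for alg in self.algorithms:
            member = make_member(alg, sre_q=self.sre_q, max_iter=self.max_iter)
            member.fit(self.env, y)
            members[alg] = member
        ensemble = build_ensemble(members, mean_auc, self.auc_cutoff)
        return EnsembleSDMResults(self, scores, ensemble)


class EnsembleSDMResults:
    """Fitted ensemble with its evaluation scores."""

    def __init__(self, model: EnsembleSDM, scores: pd.DataFrame, ensemble: Ensemble):
        self.model = model
        self.scores = scores
        self.ensemble = ensemble
        self.member_aucs = ensemble.member_aucs
        self.weights = ensemble.weights

    @property
    def variables(self) -> list[str]:
        return env_columns(self.model.env)

    def predict(self, env: pd.DataFrame) -> np.ndarray:
        return self.ensemble.predict(env)

    def predict_raster(self, stack: RasterStack) -> RasterGrid:
        return predict_raster(self.ensemble, stack, variables=self.variables)

    def response_curve(self, variable: str, n_grid: int = 101) -> ResponseCurve:
        return response_curve(self.ensemble, self.model.env, variable, n_grid)

    def suitable_range(self, variable: str, threshold: float = 0.5,
                       n_grid: int = 101) -> SuitableRange:
        return suitable_range(self.response_curve(variable, n_grid), threshold)

    def suitable_range_table(self, threshold: float = 0.5) -> pd.DataFrame:
        rows = []
        for var in self.variables:
            sr = self.suitable_range(var, threshold)
            rows.append({"variable": var, "lo": sr.lo, "hi": sr.hi,
                         "optimum": sr.optimum,
                         "max_probability": sr.max_probability})
        return pd.DataFrame(rows)

    def variable_importance(self, mode: str = "permutation", n_perm: int = 5,
                            seed: int = 0) -> pd.DataFrame:
        return variable_importance(self.ensemble, self.model.env, mode=mode,
                                   n_perm=n_perm, seed=seed)

    def summary(self) -> str:
        lines = ["Ensemble SDM results", "=" * 40]
        lines.append(f"records: {len(self.model.env)} "
                     f"({int(self.model.env['label'].sum())} presence)")
        lines.append(f"splits: {self.model.split:.2f} train fraction, "
                     f"{self.model.n_runs} runs/algorithm")
        lines.append(f"AUC cutoff for inclusion: > {self.ensemble.auc_cutoff}")
        lines.append("")
        lines.append(f"{'member':<8}{'mean AUC':>10}{'mean TSS':>10}"
                     f"{'mean kappa':>12}{'weight':>10}")
        means = self.scores.groupby("algorithm")[["auc", "tss", "kappa"]].mean()
        for alg in self.model.algorithms:
            w = self.weights.get(alg)
            row = means.loc[alg]
            wtxt = f"{w:.4f}" if w is not None else "excluded"
            lines.append(f"{alg:<8}{row['auc']:>10.4f}{row['tss']:>10.4f}"
                         f"{row['kappa']:>12.4f}{wtxt:>10}")
        return "\n".join(lines)

    def plot_response_curves(self, variables=None, threshold: float = 0.5, ax=None):
        """Response curves per variable with the suitability threshold."""
        import matplotlib.pyplot as plt

        variables = variables or self.variables
        fig, axes = plt.subplots(1, len(variables),
                                 figsize=(3.2 * len(variables), 2.8))
        axes = np.atleast_1d(axes)
        for ax_, var in zip(axes, variables):
            c = self.response_curve(var)
            ax_.plot(c.grid, c.response)
            ax_.axhline(threshold, ls="--", c="grey", lw=0.8)
            ax_.set_xlabel(var)
            ax_.set_ylim(0, 1.02)
        axes[0].set_ylabel("ensemble suitability")
        fig.tight_layout()
        return fig
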