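"""Maximum-likelihood fitting and BIC model comparison.

Each model's NB likelihood is maximized by a seeded global differential-
evolution search inside the parameter box (population 20x the number of
parameters, up to 5000 iterations by default), followed by a bounded local
refinement started from the DE optimum.  The dispersion ``alpha`` and the
smoothness ``kappa`` span twenty orders of magnitude, so the optimizer
searches their log10 — the identical feasible set with a sane metric.

The fitted optimum of each nested model is injected into the initial DE
population of every larger model (the homogeneous optimum into B/C/D, and
the step-model optimum, reparameterized with a near-infinite ``kappa``,
into the sigmoid model), which guarantees the best-found likelihood can
only improve with model complexity.

Model comparison uses BIC = 2*nll + k*ln(n) (lower is better) and its
normalized Akaike-style weights wBIC = exp(-dBIC/2) / sum(exp(-dBIC/2));
the preferred model of a (specimen, marker) cell is the lowest-BIC model,
ties broken toward fewer parameters.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .grid_io import MARKERS, SectorGrid
from .models import (N_PARAMS, ModelParams, nb_neg_loglik, param_space,
                     predict_mean)

#: parameters searched on a log10 scale (their box spans [1, 1e20])
_LOG_FIELDS = {"alpha", "kappa"}

from .models import _FIELDS  # parameter order per model


@dataclasses.dataclass
class FitOptions:
    """Optimizer budget.  The study-scale defaults are DE with population
    20x the parameter count and up to 5000 generations; tests and the
    acceptance run use a reduced ``maxiter``."""

    maxiter: int = 5000
    popsize: int = 20
    tol: float = 0.01
    refine: bool = True
    refine_method: str = "nll"  # or "lsq": squared residuals of mu


@dataclasses.dataclass
class FitResult:
    model_id: str
    params: ModelParams
    nll: float
    n: int
    k: int
    bic: float
    seed: int
    converged: bool


def _log_mask(model_id: str) -> np.ndarray:
    return np.array([f in _LOG_FIELDS for f in _FIELDS[model_id]])


def _internal_bounds(model_id: str) -> list[tuple[float, float]]:
    bounds, _ = param_space(model_id)
    out = []
    for (lo, hi), is_log in zip(bounds, _log_mask(model_id)):
        out.append((math.log10(lo), math.log10(hi)) if is_log else (lo, hi))
    return out


def _to_external(model_id: str, vec: np.ndarray) -> np.ndarray:
    ext = np.array(vec, float)
    ext[_log_mask(model_id)] = 10.0 ** ext[_log_mask(model_id)]
    return ext


def _to_internal(model_id: str, vec: np.ndarray) -> np.ndarray:
    intl = np.array(vec, float)
    m = _log_mask(model_id)
    intl[m] = np.log10(intl[m])
    return intl


def _objective(model_id: str, y: np.ndarray, coords: np.ndarray):
    def f(vec: np.ndarray) -> float:
        params = ModelParams.from_vector(model_id, _to_external(model_id, vec))
        try:
            return nb_neg_loglik(params, y, coords)
        except (ValueError, FloatingPointError):
            return 1e12
    return f


def _moment_start(model_id: str, y: np.ndarray) -> np.ndarray:
    """Method-of-moments homogeneous start: intercept from the mean count,
    dispersion from the variance-mean relation (clipped into bounds)."""
    mean = max(float(np.mean(y)), 1e-6)
    var = float(np.var(y, ddof=1)) if len(y) > 1 else mean
    alpha = mean * mean / (var - mean) if var > mean else 1e6
    alpha = float(np.clip(alpha, 1.0, 1e20))
    lam0 = float(np.clip(math.log(mean), -15.0, 200.0))
    base = {"lambda0": lam0, "alpha": alpha, "lambda1": 0.0, "lambda2": 0.0,
            "lambda3": 0.0, "beta1": 0.5, "beta2": 0.5, "tau1": 0.3,
            "tau2": 0.7, "kappa": 10.0}
    return np.array([base[f] for f in _FIELDS[model_id]], float)


def _embed(model_id: str, params: ModelParams) -> np.ndarray | None:
    """Express a fitted smaller model as a parameter vector of ``model_id``."""
    if params.model_id == "A":
        base = {"lambda0": params.lambda0, "alpha": params.alpha,
                "lambda1": 0.0, "lambda2": 0.0, "lambda3": 0.0,
                "beta1": 0.5, "beta2": 0.5, "tau1": 0.3, "tau2": 0.7,
                "kappa": 10.0}
        return np.array([base[f] for f in _FIELDS[model_id]], float)
    if params.model_id == "C" and model_id == "D":
        # step model as the kappa -> inf limit of the sigmoid model
        base = {"lambda0": params.lambda0 + params.lambda2,
                "lambda1": params.lambda1, "lambda2": -params.lambda2,
                "beta1": params.beta1, "beta2": params.beta2,
                "tau1": params.tau1, "tau2": params.tau2,
                "kappa": 1e6, "alpha": params.alpha}
        return np.array([base[f] for f in _FIELDS["D"]], float)
    return None


def fit_model(grid: SectorGrid, model_id: str, seed: int = 0,
              options: FitOptions | None = None,
              inject: Sequence[ModelParams] = ()) -> FitResult:
    """Fit one model to a grid's included sectors by DE + local refinement.

    ``inject`` holds fitted nested models whose optima are embedded into the
    initial DE population (and compared against the final optimum), so the
    best-found NLL is monotone under nesting.
    """
    options = options or FitOptions()
    y = grid.intensities()
    coords = grid.coords()
    k = N_PARAMS[model_id]
    n = len(y)
    if n <= k:
        raise ValueError(f"need more than {k} sectors to fit model {model_id}")
    identifiable = model_id == "A" or np.unique(y).size > 1

    f = _objective(model_id, y, coords)
    bounds = _internal_bounds(model_id)
    rng = np.random.default_rng(seed)
    pop_size = max(options.popsize * k, 5)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    init = lo + (hi - lo) * rng.random((pop_size, k))
    starts = [_moment_start(model_id, y)]
    starts += [v for v in (_embed(model_id, p) for p in inject) if v is not None]
    for r, sv in enumerate(starts[:pop_size]):
        init[r] = np.clip(_to_internal(model_id, sv), lo, hi)

    de = optimize.differential_evolution(
        f, bounds, maxiter=options.maxiter, popsize=options.popsize,
        init=init, seed=int(rng.integers(2 ** 31)), tol=options.tol,
        polish=False)
    best_x, best_nll = de.x, float(de.fun)

    if options.refine:
        best_x, best_nll = _refine(f, model_id, y, coords, best_x, best_nll,
                                   bounds, options)
    # the injected optima are hard floors: never report worse than them
    for sv in starts[1:]:
        xv = np.clip(_to_internal(model_id, sv), lo, hi)
        fv = f(xv)
        if fv < best_nll:
            best_x, best_nll = xv, fv

    params = ModelParams.from_vector(model_id, _to_external(model_id, best_x))
    return FitResult(model_id=model_id, params=params, nll=best_nll, n=n,
                     k=k, bic=bic(best_nll, k, n), seed=seed,
                     converged=bool(de.success or options.refine) and identifiable)


def _refine(f, model_id, y, coords, x0, f0, bounds, options: FitOptions):
    if options.refine_method == "lsq":
        def resid(vec):
            params = ModelParams.from_vector(model_id, _to_external(model_id, vec))
            return predict_mean(params, coords) - y
        res = optimize.least_squares(resid, x0, bounds=([b[0] for b in bounds],
                                                        [b[1] for b in bounds]))
        x1 = res.x
    else:
        res = optimize.minimize(f, x0, method="L-BFGS-B", bounds=bounds)
        x1 = res.x
    f1 = f(x1)
    return (x1, f1) if f1 < f0 else (x0, f0)


# ---------------------------------------------------------------------------
# information criteria

def bic(nll: float, k: int, n: int) -> float:
    """Bayesian information criterion, 2*nll + k*ln(n); lower is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * nll + k * math.log(n)


def wbic_weights(bics: Sequence[float]) -> np.ndarray:
    """Normalized BIC weights exp(-dBIC/2)/sum, computed on deltas."""
    b = np.asarray(bics, float)
    finite = np.isfinite(b)
    if not finite.any():
        raise ValueError("all BIC values are infinite")
    w = np.zeros_like(b)
    d = b[finite] - b[finite].min()
    e = np.exp(-0.5 * d)
    w[finite] = e / e.sum()
    return w


# ---------------------------------------------------------------------------
# model comparison and preference tables

_MODEL_ORDER = ("A", "B", "C", "D")


def preferred_model(bics: Mapping[str, float]) -> str:
    """Lowest-BIC model; exact ties go to fewer parameters, then to the
    alphabetically first id."""
    return min(bics, key=lambda m: (bics[m], N_PARAMS[m], m))


def compare_models(grid: SectorGrid, seed: int = 0,
                   options: FitOptions | None = None,
                   models: Sequence[str] = _MODEL_ORDER) -> dict:
    """Fit all candidate models to one grid and pick the preferred one.

    Models are fitted smallest-first so every nested optimum seeds the
    larger searches.  Returns a row dict with per-model nll/bic/wbic, the
    fitted parameters, and the preferred model (lowest BIC; ties go to the
    model with fewer parameters, then alphabetically).
    """
    options = options or FitOptions()
    ss = np.random.SeedSequence(seed)
    fits: dict[str, FitResult] = {}
    for m, sub in zip(models, ss.spawn(len(models))):
        inject = [fits[prev].params for prev in fits]
        fits[m] = fit_model(grid, m, seed=int(sub.generate_state(1)[0] % 2 ** 31),
                            options=options, inject=inject)
    bics = {m: fits[m].bic for m in models}
    weights = wbic_weights([bics[m] for m in models])
    preferred = preferred_model(bics)
    return {"specimen": grid.specimen_id, "marker": grid.marker,
            "fits": fits, "bic": bics,
            "wbic": dict(zip(models, weights)), "preferred": preferred,
            "complete": all(fits[m].converged for m in models)}


@dataclasses.dataclass
class PreferenceTable:
    """Per-(specimen, marker) BIC weights and winners, with margins."""

    rows: pd.DataFrame  # specimen, marker, bic_*, wbic_*, preferred

    def label_grid(self) -> pd.DataFrame:
        """Specimens x markers grid of preferred-model labels."""
        return self.rows.pivot(index="specimen", columns="marker",
                               values="preferred")


def build_preference_table(results: Sequence[Mapping]) -> PreferenceTable:
    rows = []
    for r in results:
        row = {"specimen": r["specimen"], "marker": r["marker"],
               "preferred": r["preferred"]}
        for m in r["bic"]:
            row[f"bic_{m}"] = r["bic"][m]
            row[f"wbic_{m}"] = r["wbic"][m]
        rows.append(row)
    return PreferenceTable(pd.DataFrame(rows))


def tally_preferences(labels: pd.DataFrame) -> dict[str, float]:
    """Percentage of (specimen, marker) cells preferring each model.

    ``labels`` is a specimens x markers grid of model labels (or any frame
    of labels); percentages are over all non-null cells and sum to 100.
    """
    flat = labels.to_numpy().ravel()
    flat = flat[pd.notna(flat)]
    if flat.size == 0:
        raise ValueError("empty preference grid")
    out = {}
    for m in _MODEL_ORDER:
        out[m] = 100.0 * float((flat == m).sum()) / flat.size
    return out


def aggregate_preferences(table: PreferenceTable) -> dict:
    """Margin winners by highest mean wBIC: per specimen (across markers),
    per marker (across specimens), and overall."""
    rows = table.rows
    wcols = [c for c in rows.columns if c.startswith("wbic_")]
    models = [c.removeprefix("wbic_") for c in wcols]

    def winner(df: pd.DataFrame) -> str:
        means = {m: df[f"wbic_{m}"].mean() for m in models}
        return min(models, key=lambda m: (-means[m], N_PARAMS[m], m))

    per_specimen = {s: winner(g) for s, g in rows.groupby("specimen")}
    per_marker = {m: winner(g) for m, g in rows.groupby("marker")}
    return {"per_specimen": per_specimen, "per_marker": per_marker,
            "overall": winner(rows)}


#: Preferred-model labels reported for the seven-specimen, twelve-marker
#: post-mortem study (rows: specimens; columns: the twelve protein markers).
#: Used as a reference input for tallies; B = linear gradient, C = three
#: subdivisions, D = sigmoidal gradient.
STUDY_PREFERRED_MODELS = pd.DataFrame(
    [list(r) for r in [
        "BBDBDDCBDBDB",
        "BBBBBBBBDDBD",
        "BDBBDDBBDBDB",
        "BBBBDBBCCCCD",
        "BBBBBBBBBBBB",
        "BCDBBDBDBBBC",
        "BBDBDDBDDDBD",
    ]],
    index=["13-095", "14-037", "14-051", "14-069", "15-033", "15-035", "15-055"],
    columns=MARKERS,
)
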