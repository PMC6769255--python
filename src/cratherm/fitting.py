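"""Multi-start correlation fitting of the occupancy model to expression data.

The objective is the Pearson correlation between modelled RNAPII occupancy
probabilities and observed relative expression across experimental
conditions.  Because the correlation surface has many local optima, fitting
runs from many random starts with two bound-constrained optimizers — a
quasi-Newton method (L-BFGS-B) and a derivative-free Hooke-Jeeves pattern
search — and keeps the whole ensemble.  Parameter sets whose correlation is
within a tolerance (default 0.1) of the best found form the selected
ensemble; its per-parameter mean and 2.5/97.5 percentile interval are the
reported estimates.  The ensemble characterises, rather than pinpoints, the
energies: distinct parameter sets can produce identical occupancy vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model import (
    ACTIVATION,
    ExperimentalState,
    ModelSpec,
    ParameterSet,
    state_design_matrix,
)

__all__ = [
    "ExpressionTable",
    "FitResult",
    "FitEnsemble",
    "objective",
    "fit_multistart",
    "select_ensemble",
    "summarize_ensemble",
    "hooke_jeeves",
    "EnhancerActivationModel",
    "ActivationFitResults",
]

DEFAULT_BOUNDS = (-5.0, 5.0)
DEFAULT_TOLERANCE = 0.1


class ExpressionTable:
    """Observed relative expression per experimental condition.

    Wraps a DataFrame with one row per condition: columns ``targeted``
    (label such as "1+3" or "control"), ``mode``, ``mean_rel_expression``,
    ``sem``, ``n_replicates`` and optionally ``gene``.
    """

    REQUIRED = ["targeted", "mode", "mean_rel_expression", "sem", "n_replicates"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"ExpressionTable missing columns: {missing}")
        frame = frame.reset_index(drop=True)
        states = [
            ExperimentalState.from_label(row.targeted, row.mode)
            for row in frame.itertuples()
        ]
        if len(set(states)) != len(states):
            raise ValueError("duplicate experimental states in table")
        if len(states) < 3:
            raise ValueError("need >= 3 distinct experimental states")
        if (frame["mean_rel_expression"] <= 0).any():
            raise ValueError("relative expression values must be positive")
        self.frame = frame
        self._states = states

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def states(self) -> list[ExperimentalState]:
        return list(self._states)

    @property
    def values(self) -> np.ndarray:
        return self.frame["mean_rel_expression"].to_numpy(dtype=float)

    @classmethod
    def from_records(cls, records, mode: str = ACTIVATION, gene: str | None = None):
        """Build from (label, mean, sem, n) tuples or (state, mean, sem, n)."""
        rows = []
        for state, mean, sem, n in records:
            label = state.to_label() if isinstance(state, ExperimentalState) else str(state)
            m = state.mode if isinstance(state, ExperimentalState) else mode
            rows.append(
                {"targeted": label, "mode": m, "mean_rel_expression": mean, "sem": sem, "n_replicates": n}
            )
        frame = pd.DataFrame(rows)
        if gene is not None:
            frame.insert(0, "gene", gene)
        return cls(frame)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def without_control(self) -> "ExpressionTable":
        keep = self.frame["targeted"].str.lower() != "control"
        return ExpressionTable(self.frame[keep])

    def max_site_index(self) -> int:
        return max((max(s.targeted) for s in self._states if s.targeted), default=-1)


@dataclass
class FitResult:
    """One locally optimal parameter set from one start of one algorithm."""

    params: ParameterSet
    objective: float
    algorithm: str
    start_index: int
    converged: bool


@dataclass
class FitEnsemble:
    """All fits from a multi-start run plus the near-optimal selection."""

    fits: list[FitResult]
    tolerance: float = DEFAULT_TOLERANCE
    selected: list[FitResult] = field(init=False)

    def __post_init__(self) -> None:
        if not self.fits:
            raise ValueError("ensemble needs at least one fit")
        best = self.best_objective
        self.selected = [f for f in self.fits if f.objective >= best - self.tolerance]

    @property
    def best_objective(self) -> float:
        return max(f.objective for f in self.fits)

    @property
    def best(self) -> FitResult:
        return max(self.fits, key=lambda f: f.objective)

    def selected_matrix(self) -> np.ndarray:
        return np.array([f.params.to_vector() for f in self.selected])

    def to_dict(self) -> dict:
        best = self.best_objective
        return {
            "tolerance": self.tolerance,
            "best_objective": best,
            "fits": [
                {
                    "params": f.params.to_dict(),
                    "objective": f.objective,
                    "algorithm": f.algorithm,
                    "start_index": f.start_index,
                    "converged": f.converged,
                    "selected": f.objective >= best - self.tolerance,
                }
                for f in self.fits
            ],
        }


class _PartitionEvaluator:
    """Vectorised p(RNAPII) over a fixed list of experimental states.

    Stacks the per-condition state design matrices once so each objective
    evaluation is a single mat-vec plus grouped log-sum-exps.
    """

    def __init__(self, spec: ModelSpec, states: list[ExperimentalState]):
        self.spec = spec
        blocks, bounds_mask, slices = [], [], []
        offset = 0
        for st in states:
            a, bound = state_design_matrix(spec, st)
            blocks.append(a)
            bounds_mask.append(bound)
            slices.append((offset, offset + a.shape[0]))
            offset += a.shape[0]
        self.design = np.vstack(blocks)
        self.bound = np.concatenate(bounds_mask)
        self.slices = slices
        self.rt = spec.rt

    def probabilities(self, theta: np.ndarray) -> np.ndarray:
        log_w = -(self.design @ theta) / self.rt
        out = np.empty(len(self.slices))
        for k, (lo, hi) in enumerate(self.slices):
            a = log_w[lo:hi]
            b = self.bound[lo:hi]
            m = a.max()
            ea = np.exp(a - m)
            out[k] = ea[b].sum() / ea.sum()
        return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0 or not np.isfinite(denom):
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def objective(params: ParameterSet, table: ExpressionTable, spec: ModelSpec) -> float:
    """Pearson correlation between modelled occupancy and observed expression.

    A model vector with zero variance (the correlation is undefined) scores
    -1 by convention, which keeps the optimizers out of flat regions.
    """
    ev = _PartitionEvaluator(spec, table.states)
    return _objective_theta(params.to_vector(), ev, table.values)


def _objective_theta(theta: np.ndarray, ev: _PartitionEvaluator, expr: np.ndarray) -> float:
    r = _pearson(ev.probabilities(theta), expr)
    return -1.0 if np.isnan(r) else r


def hooke_jeeves(
    fun,
    x0: np.ndarray,
    bounds: tuple[float, float],
    step: float = 1.0,
    step_tol: float = 1e-4,
    max_evals: int = 2000,
):
    """Minimise ``fun`` by Hooke-Jeeves pattern search within a box.

    Exploratory coordinate moves around a base point, followed by a pattern
    (extrapolation) move when the exploration improved; the step halves when
    no move helps.  Iterates are projected onto ``[lo, hi]`` per coordinate.
    Returns ``(x_best, f_best, n_evals, converged)`` where ``converged``
    means the step-size tolerance was reached within the evaluation budget.
    """
    lo, hi = bounds
    clip = lambda x: np.clip(x, lo, hi)
    x = clip(np.asarray(x0, dtype=float).copy())
    n_evals = 0

    def f(v):
        nonlocal n_evals
        n_evals += 1
        return fun(v)

    fx = f(x)

    def explore(base, fbase):
        pt = base.copy()
        fpt = fbase
        for i in range(pt.size):
            for delta in (step, -step):
                trial = pt.copy()
                trial[i] = np.clip(trial[i] + delta, lo, hi)
                if trial[i] == pt[i]:
                    continue
                ft = f(trial)
                if ft < fpt:
                    pt, fpt = trial, ft
                    break
                if n_evals >= max_evals:
                    return pt, fpt
        return pt, fpt

    while step >= step_tol and n_evals < max_evals:
        x_new, f_new = explore(x, fx)
        if f_new < fx:
            # pattern move: extrapolate along the successful direction
            while n_evals < max_evals:
                x_pat = clip(x_new + (x_new - x))
                x, fx = x_new, f_new
                x_try, f_try = explore(x_pat, f(x_pat))
                if f_try < fx:
                    x_new, f_new = x_try, f_try
                else:
                    break
        else:
            step /= 2.0
    return x, fx, n_evals, step < step_tol


def fit_multistart(
    table: ExpressionTable,
    spec: ModelSpec,
    n_starts: int,
    seed: int,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tolerance: float = DEFAULT_TOLERANCE,
) -> FitEnsemble:
    """Fit from ``n_starts`` random starts with both optimizers.

    Starts are drawn uniformly within ``bounds`` per coordinate from a
    seeded generator (per-start seeds spawned from the master seed, so the
    ensemble is reproducible and order-independent).  Each start is refined
    by L-BFGS-B and, independently, by Hooke-Jeeves pattern search, both
    minimising the negative correlation within the box; the ensemble holds
    all ``2 * n_starts`` fits.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")

    ev = _PartitionEvaluator(spec, table.states)
    expr = table.values
    neg = lambda theta: -_objective_theta(theta, ev, expr)
    n_par = spec.n_parameters
    child_seeds = np.random.SeedSequence(seed).spawn(n_starts)

    fits: list[FitResult] = []
    for k in range(n_starts):
        rng = np.random.default_rng(child_seeds[k])
        x0 = rng.uniform(lo, hi, size=n_par)

        res = optimize.minimize(
            neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * n_par
        )
        fits.append(
            FitResult(
                ParameterSet.from_vector(res.x, spec.n_sites),
                float(-res.fun),
                "l-bfgs-b",
                k,
                bool(res.success),
            )
        )

        x_hj, f_hj, _, conv = hooke_jeeves(neg, x0, bounds)
        fits.append(
            FitResult(
                ParameterSet.from_vector(x_hj, spec.n_sites),
                float(-f_hj),
                "hooke-jeeves",
                k,
                conv,
            )
        )
    return FitEnsemble(fits, tolerance)


def select_ensemble(fits: list[FitResult], tolerance: float = DEFAULT_TOLERANCE) -> FitEnsemble:
    """Keep the fits within ``tolerance`` of the best correlation found."""
    if not fits:
        raise ValueError("no fits to select from")
    return FitEnsemble(list(fits), tolerance)


def summarize_ensemble(ensemble: FitEnsemble, n_bins: int = 20) -> pd.DataFrame:
    """Per-parameter mean, 2.5/97.5 percentile interval and histogram.

    Percentile (not normal-theory) intervals are used because selected
    ensembles are frequently multimodal.
    """
    mat = ensemble.selected_matrix()
    names = ensemble.selected[0].params.parameter_names()
    lo, hi = np.percentile(mat, [2.5, 97.5], axis=0)
    rows = []
    for j, name in enumerate(names):
        counts, edges = np.histogram(mat[:, j], bins=n_bins)
        rows.append(
            {
                "parameter": name,
                "mean": mat[:, j].mean(),
                "ci_low": lo[j],
                "ci_high": hi[j],
                "hist_counts": counts.tolist(),
                "hist_edges": edges.tolist(),
            }
        )
    return pd.DataFrame(rows)


class EnhancerActivationModel:
    """Occupancy model bound to one gene's combinatorial expression data.

    Follows the model/results idiom: construct from data, call :meth:`fit`,
    inspect the returned :class:`ActivationFitResults`.

    Parameters
    ----------
    table : ExpressionTable
        Relative expression per experimental condition.
    spec : ModelSpec, optional
        Inferred from the largest site label in the table when omitted.
    include_control : bool
        Whether the untargeted control condition (relative expression 1)
        enters the fitted vector (default True; it anchors the baseline).
    """

    def __init__(
        self,
        table: ExpressionTable,
        spec: ModelSpec | None = None,
        include_control: bool = True,
    ):
        if not include_control:
            table = table.without_control()
        if spec is None:
            spec = ModelSpec(table.max_site_index() + 1)
        self.table = table
        self.spec = spec
        self.include_control = include_control

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "EnhancerActivationModel":
        return cls(ExpressionTable(frame), **kwargs)

    @classmethod
    def from_tsv(cls, path, gene: str | None = None, **kwargs) -> "EnhancerActivationModel":
        frame = pd.read_csv(path, sep="\t")
        if gene is not None and "gene" in frame.columns:
            frame = frame[frame["gene"] == gene]
        return cls(ExpressionTable(frame), **kwargs)

    def predict(self, params: ParameterSet) -> np.ndarray:
        """Modelled p(RNAPII) for every condition in the table."""
        return _PartitionEvaluator(self.spec, self.table.states).probabilities(
            params.to_vector()
        )

    def score(self, params: ParameterSet) -> float:
        return objective(params, self.table, self.spec)

    def fit(
        self,
        n_starts: int = 1000,
        seed: int = 0,
        bounds: tuple[float, float] = DEFAULT_BOUNDS,
        tolerance: float = DEFAULT_TOLERANCE,
    ) -> "ActivationFitResults":
        ensemble = fit_multistart(self.table, self.spec, n_starts, seed, bounds, tolerance)
        return ActivationFitResults(self, ensemble)


class ActivationFitResults:
    """Fitted ensemble with statsmodels-flavoured accessors."""

    def __init__(self, model: EnhancerActivationModel, ensemble: FitEnsemble):
        self.model = model
        self.ensemble = ensemble

    @property
    def best_params(self) -> ParameterSet:
        return self.ensemble.best.params

    @property
    def params(self) -> pd.Series:
        """Mean of each energy over the selected ensemble."""
        mat = self.ensemble.selected_matrix()
        names = self.best_params.parameter_names()
        return pd.Series(mat.mean(axis=0), index=names, name="mean")

    @property
    def rsquared_like(self) -> float:
        """Best Pearson correlation achieved (the fitting objective)."""
        return self.ensemble.best_objective

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        mat = self.ensemble.selected_matrix()
        lo, hi = np.percentile(mat, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
        return pd.DataFrame(
            {"ci_low": lo, "ci_high": hi}, index=self.best_params.parameter_names()
        )

    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.best_params)

    def summary(self) -> str:
        ens = self.ensemble
        ci = self.conf_int()
        lines = [
            "Enhancer activation occupancy model — multi-start fit",
            "=" * 56,
            f"conditions fitted:    {len(self.model.table)}",
            f"fits (starts x alg):  {len(ens.fits)}",
            f"selected (tol {ens.tolerance:.2f}):  {len(ens.selected)}",
            f"best Pearson r:       {ens.best_objective:.4f}",
            "-" * 56,
            f"{'parameter':<14}{'mean':>10}{'2.5%':>10}{'97.5%':>10}",
        ]
        for name, mean in self.params.items():
            lines.append(
                f"{name:<14}{mean:>10.3f}{ci.loc[name, 'ci_low']:>10.3f}{ci.loc[name, 'ci_high']:>10.3f}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot_param_distributions(self, bins: int = 20):
        """Histogram of each parameter over the selected ensemble."""
        import matplotlib.pyplot as plt

        mat = self.ensemble.selected_matrix()
        names = self.best_params.parameter_names()
        ncol = 4
        nrow = int(np.ceil(len(names) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow))
        for ax, j in zip(np.ravel(axes), range(len(names))):
            ax.hist(mat[:, j], bins=bins, color="steelblue")
            ax.axvline(mat[:, j].mean(), color="black")
            ax.set_title(names[j], fontsize=9)
        for ax in np.ravel(axes)[len(names):]:
            ax.set_visible(False)
        fig.tight_layout()
        return fig
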