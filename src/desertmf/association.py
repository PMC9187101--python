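"""Bivariate regression screens and recursive path analysis.

Two layers of driver analysis over the per-plot table:

* :func:`ols_screen` — linear and quadratic ("single-peak") least-squares
  fits of one response on one predictor, with R² and the overall-F p-value.
* :func:`fit_path_model` — a recursive observed-variable path model (a DAG
  of standardized regressions).  For such models, equation-wise least
  squares on standardized variables is exact maximum likelihood, so no
  general SEM optimizer is needed.  Model fit is summarized by the
  likelihood-ratio chi-square against the sample correlation matrix, the
  normed chi-square NC = χ²/df, and the comparative fit index CFI against
  the independence baseline.

Sample correlations among exogenous variables are treated as fixed (not
free parameters) when counting degrees of freedom; SEM software that frees
them will report slightly different NC/CFI for the same edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "PathModel",
    "PathEdge",
    "PathFit",
    "ols_screen",
    "fit_path_model",
    "indirect_effect",
    "direct_effect",
    "total_effect",
]


@dataclass(frozen=True)
class RegressionFit:
    predictor: str
    response: str
    form: str                 # "linear" | "quadratic"
    coefficients: dict        # {"intercept": ..., "x": ..., ["x2": ...]}
    r2: float
    p_value: float            # overall F-test
    n: int


def ols_screen(y, x, form: str = "linear", predictor: str = "x",
               response: str = "y") -> RegressionFit:
    """Least-squares screen of one response against one predictor.

    ``form='quadratic'`` adds x² to capture single-peak (hump-shaped)
    relations; its R² is never below the linear fit's on the same data.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if form not in ("linear", "quadratic"):
        raise ValueError(f"unknown form {form!r}")
    n_params = 2 if form == "linear" else 3
    if len(y) <= n_params + 1:
        raise ValueError("too few observations for the requested form")
    if np.std(x) == 0:
        raise ValueError(f"predictor '{predictor}' is constant")
    cols = [x] if form == "linear" else [x, x**2]
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (predictor and its square are collinear)")
    fit = sm.OLS(y, X).fit()
    names = ["intercept", "x"] + (["x2"] if form == "quadratic" else [])
    return RegressionFit(
        predictor=predictor, response=response, form=form,
        coefficients=dict(zip(names, map(float, fit.params))),
        r2=float(fit.rsquared), p_value=float(fit.f_pvalue), n=int(len(y)),
    )


@dataclass(frozen=True)
class PathModel:
    """A DAG of directed effects among observed variables."""

    edges: tuple

    def __post_init__(self):
        edges = tuple((str(a), str(b)) for a, b in self.edges)
        object.__setattr__(self, "edges", edges)
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model contains a cycle; only recursive (DAG) models are supported")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    @property
    def variables(self) -> tuple:
        seen = []
        for a, b in self.edges:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    @property
    def endogenous(self) -> tuple:
        targets = {b for _, b in self.edges}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple:
        targets = {b for _, b in self.edges}
        return tuple(v for v in self.variables if v not in targets)

    @classmethod
    def from_strings(cls, lines) -> "PathModel":
        """Parse 'source -> target' lines (the plain-text model format)."""
        edges = []
        for line in lines:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "->" not in line:
                raise ValueError(f"cannot parse path edge {line!r}; expected 'source -> target'")
            src, tgt = (part.strip() for part in line.split("->", 1))
            edges.append((src, tgt))
        return cls(edges=tuple(edges))


@dataclass(frozen=True)
class PathEdge:
    source: str
    target: str
    coefficient: float        # standardized
    se: float
    p_value: float


@dataclass(frozen=True)
class PathFit:
    model: PathModel
    edges: tuple              # of PathEdge
    residual_variances: dict  # endogenous variable -> 1 − R²
    implied: pd.DataFrame     # model-implied correlation matrix
    chi2: float
    df: int
    nc: float                 # χ²/df (0 for saturated models)
    cfi: float
    n: int
    heywood: tuple = field(default=())  # edges with |coef| > 1

    def coefficient(self, source: str, target: str) -> float:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e.coefficient
        raise KeyError(f"no edge {source} -> {target} in model")


def fit_path_model(model: PathModel, data: pd.DataFrame) -> PathFit:
    """Fit a recursive path model by equation-wise OLS on standardized data.

    Every endogenous variable is regressed on its parents; path coefficients
    are the standardized slopes with t-based p-values.  The implied
    correlation matrix is assembled from the structural equations
    (Σ = (I−B)⁻¹ Ψ (I−B)⁻ᵀ with exogenous correlations fixed at their
    sample values and independent errors), and χ² = (n−1)·F_ML compares it
    with the sample correlation matrix.
    """
    variables = list(model.variables)
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"data is missing model variables: {', '.join(missing)}")
    n = len(data)
    if n <= len(variables) + 2:
        raise ValueError("too few observations for the model size")
    raw = data[variables].to_numpy(dtype=float)
    sds = raw.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        const = [variables[i] for i in np.flatnonzero(sds <= 0)]
        raise ValueError(f"constant model variables: {', '.join(const)}")
    Z = (raw - raw.mean(axis=0)) / sds
    zcols = {v: Z[:, i] for i, v in enumerate(variables)}
    S = np.corrcoef(Z, rowvar=False)
    if np.linalg.matrix_rank(S) < len(variables):
        raise ValueError("singular sample correlation matrix")

    pos = {v: i for i, v in enumerate(variables)}
    p = len(variables)
    B = np.zeros((p, p))
    edges = []
    resid = {}
    g = model.graph()
    for v in model.endogenous:
        parents = sorted(g.predecessors(v), key=pos.get)
        X = sm.add_constant(np.column_stack([zcols[u] for u in parents]))
        fit = sm.OLS(zcols[v], X).fit()
        for u, coef, se, pval in zip(parents, fit.params[1:], fit.bse[1:], fit.pvalues[1:]):
            B[pos[v], pos[u]] = coef
            edges.append(PathEdge(u, v, float(coef), float(se), float(pval)))
        resid[v] = float(max(1.0 - fit.rsquared, 0.0))

    Psi = np.zeros((p, p))
    exo_idx = [pos[v] for v in model.exogenous]
    Psi[np.ix_(exo_idx, exo_idx)] = S[np.ix_(exo_idx, exo_idx)]
    for v, rv in resid.items():
        Psi[pos[v], pos[v]] = rv
    IB = np.linalg.inv(np.eye(p) - B)
    Sigma = IB @ Psi @ IB.T

    n_free = len(model.edges) + len(model.endogenous) + len(model.exogenous)
    df = p * (p + 1) // 2 - n_free
    if df < 0:
        raise ValueError("model has more free parameters than moments")
    if df == 0:
        chi2, nc, cfi = 0.0, 0.0, 1.0
    else:
        sign, logdet_sigma = np.linalg.slogdet(Sigma)
        if sign <= 0:
            raise ValueError("implied matrix is not positive definite")
        _, logdet_s = np.linalg.slogdet(S)
        fml = logdet_sigma - logdet_s + float(np.trace(S @ np.linalg.inv(Sigma))) - p
        chi2 = max((n - 1) * fml, 0.0)
        nc = chi2 / df
        chi2_b = -(n - 1) * logdet_s
        df_b = p * (p - 1) // 2
        denom = max(chi2_b - df_b, chi2 - df, 1e-12)
        cfi = float(np.clip(1.0 - max(chi2 - df, 0.0) / denom, 0.0, 1.0))

    heywood = tuple(e for e in edges if abs(e.coefficient) > 1.0)
    implied = pd.DataFrame(Sigma, index=variables, columns=variables)
    return PathFit(model=model, edges=tuple(edges), residual_variances=resid,
                   implied=implied, chi2=float(chi2), df=int(df), nc=float(nc),
                   cfi=float(cfi), n=n, heywood=heywood)


def direct_effect(fit: PathFit, source: str, target: str) -> float:
    """The standardized coefficient on source→target, or 0 if no such edge."""
    try:
        return fit.coefficient(source, target)
    except KeyError:
        return 0.0


def indirect_effect(fit: PathFit, source: str, target: str) -> float:
    """Sum over all multi-edge directed paths of the product of coefficients."""
    g = fit.model.graph()
    if source not in g or target not in g:
        return 0.0
    total = 0.0
    for path in nx.all_simple_paths(g, source, target):
        if len(path) < 3:
            continue
        prod = 1.0
        for a, b in zip(path[:-1], path[1:]):
            prod *= fit.coefficient(a, b)
        total += prod
    return total


def total_effect(fit: PathFit, source: str, target: str) -> float:
    return direct_effect(fit, source, target) + indirect_effect(fit, source, target)
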