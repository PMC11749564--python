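"""Constrained ordination of expression against environmental covariates.

Canonical correspondence analysis: the response matrix is chi-square
standardized, projected by weighted least squares onto the (weighted,
centered) environmental constraints, and the fitted matrix is
eigen-decomposed via SVD. Eigenvalues, total inertia and the
constrained proportion follow the standard correspondence-analysis
conventions; scores use the "scaling 2" convention, and axis signs are
canonicalized (first non-zero species loading positive) for
reproducibility. Collinear constraints are dropped with a warning and
reported as aliased.

Transformed (signed) expression values are made non-negative by a
global shift before entering the chi-square standardization; the shift
convention is recorded in the result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Covariates used by default; rainfall and nutrients are excluded.
DEFAULT_COVARIATES = ("par", "salinity", "temperature", "fluorescence", "turbidity", "tidal_amplitude")


@dataclass
class CCAResult:
    eigenvalues: np.ndarray
    total_inertia: float
    sample_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    aliased: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def constrained_inertia(self) -> float:
        return float(self.eigenvalues.sum())

    @property
    def proportion_constrained(self) -> float:
        return self.constrained_inertia / self.total_inertia

    def summary(self) -> str:
        lines = [
            "Canonical correspondence analysis",
            f"total inertia: {self.total_inertia:.6f}",
            f"constrained inertia: {self.constrained_inertia:.6f} "
            f"({100 * self.proportion_constrained:.1f}%)",
            "eigenvalues: " + ", ".join(f"{v:.6f}" for v in self.eigenvalues),
        ]
        if self.aliased:
            lines.append(f"aliased (dropped) constraints: {', '.join(self.aliased)}")
        return "\n".join(lines)


def prepare_response(transformed: pd.DataFrame) -> pd.DataFrame:
    """Shift a signed transformed matrix to be non-negative.

    Correspondence analysis needs non-negative input; values are shifted
    by the global minimum (when negative) so the minimum becomes exactly
    0. Already non-negative input is returned unchanged.
    """
    if not np.isfinite(transformed.to_numpy()).all():
        raise ValueError("transformed matrix must be finite")
    lo = float(transformed.to_numpy().min())
    if lo >= 0:
        return transformed
    return transformed - lo


def cca(response: pd.DataFrame, constraints: pd.DataFrame) -> CCAResult:
    """Canonical correspondence analysis of ``response`` on ``constraints``.

    Parameters
    ----------
    response
        samples x genes non-negative matrix with positive row and column
        sums.
    constraints
        samples x variables covariate table (numeric).
    """
    Y = response.to_numpy(float)
    if (Y < 0).any():
        raise ValueError("response must be non-negative")
    if (Y.sum(axis=1) <= 0).any() or (Y.sum(axis=0) <= 0).any():
        raise ValueError("response requires positive row and column sums")
    X = constraints.loc[response.index].to_numpy(float)
    n, v = X.shape
    if n <= v:
        raise ValueError("need more samples than constraint variables")

    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    Qbar = (P - expected) / np.sqrt(expected)
    total_inertia = float((Qbar**2).sum())

    # weighted centering/standardization of constraints, aliased columns dropped
    xw_mean = (r[:, None] * X).sum(axis=0)
    Xc = X - xw_mean
    sd = np.sqrt((r[:, None] * Xc**2).sum(axis=0))
    keep = sd > 1e-12
    aliased = [str(cn) for cn, k in zip(constraints.columns, keep) if not k]
    Xc = Xc[:, keep] / sd[keep]
    cols = [str(cn) for cn, k in zip(constraints.columns, keep) if k]

    Xw = np.sqrt(r)[:, None] * Xc
    keep_idx = _independent_columns(Xw)
    if len(keep_idx) < Xw.shape[1]:
        dropped = [cols[i] for i in range(Xw.shape[1]) if i not in set(keep_idx)]
        aliased += dropped
        warnings.warn(f"dropping aliased constraints: {dropped}", RuntimeWarning, stacklevel=2)
        Xw = Xw[:, keep_idx]
        cols = [cols[i] for i in keep_idx]
    q, _ = np.linalg.qr(Xw)
    Qfit = q @ (q.T @ Qbar)

    U, d, Vt = np.linalg.svd(Qfit, full_matrices=False)
    pos = d**2 > 1e-12 * max(1.0, total_inertia)
    naxes = max(int(pos.sum()), 0)
    U, d, Vt = U[:, :naxes], d[:naxes], Vt[:naxes]

    # canonical signs: first non-zero species loading positive per axis
    for i in range(naxes):
        vrow = Vt[i]
        nz = np.nonzero(np.abs(vrow) > 1e-12)[0]
        if len(nz) and vrow[nz[0]] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0

    eig = d**2
    axes = [f"CCA{i + 1}" for i in range(naxes)]
    # scaling 2: species scaled by singular values, sites as LC scores
    species = (Vt.T * d[None, :]) / np.sqrt(c)[:, None]
    sites = U / np.sqrt(r)[:, None]
    sample_scores = pd.DataFrame(sites, index=response.index, columns=axes)
    species_scores = pd.DataFrame(species, index=response.columns, columns=axes)

    # biplot scores: weighted correlations of constraints with site axes
    bip = np.zeros((len(cols), naxes))
    for i in range(naxes):
        z = U[:, i]  # weighted site scores on sqrt(r) scale
        for j in range(len(cols)):
            xj = Xw[:, j]
            bip[j, i] = float(xj @ z / np.sqrt((xj**2).sum() * (z**2).sum()))
    biplot_scores = pd.DataFrame(bip, index=cols, columns=axes)

    return CCAResult(
        eigenvalues=eig,
        total_inertia=total_inertia,
        sample_scores=sample_scores,
        species_scores=species_scores,
        biplot_scores=biplot_scores,
        aliased=aliased,
        metadata={"response_shift": "global-minimum shift applied upstream by prepare_response"},
    )


def _independent_columns(a: np.ndarray, rtol: float = 1e-9) -> list:
    """Greedy left-to-right selection of linearly independent columns,
    so earlier covariates take precedence and later ones are aliased."""
    keep: list = []
    for j in range(a.shape[1]):
        cand = a[:, keep + [j]]
        s = np.linalg.svd(cand, compute_uv=False)
        if s[-1] > rtol * max(s[0], 1.0):
            keep.append(j)
    return keep
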