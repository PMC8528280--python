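"""Directed interaction matrices from pairwise transfer entropy.

For every ordered species pair the source->target delay is selected by
maximizing lagged mutual information, transfer entropy is computed at that
delay, and negatives are clamped.  The resulting nonnegative weighted matrix
(zero diagonal; self-interactions are never computed) is then thresholded:
either at a fixed value (default 0.01 bits), by keeping the top 20% of
off-diagonal entries (the Pareto-principle core), or at the threshold whose
induced effective diversity best predicts the observed taxonomic diversity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import NormalizedAbundance
from . import infodynamics as info

__all__ = [
    "InteractionMatrix",
    "OTEProfile",
    "infer_matrix",
    "apply_threshold",
    "optimize_threshold",
    "effective_alpha",
    "ote_profile",
    "degree_stats",
    "export_network",
    "import_edge_list",
]

THRESHOLD_MODES = ("fixed", "pareto20", "alpha_opt", "none")


@dataclass
class InteractionMatrix:
    """n x n nonnegative TE matrix with inference provenance."""

    W: np.ndarray
    delays: np.ndarray
    estimator: str = "gaussian"
    threshold: float = 0.0
    threshold_mode: str = "none"
    window_id: object = None
    species: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        n, m = self.W.shape
        if n != m:
            raise ValueError("interaction matrix must be square")
        if np.any(self.W < 0):
            raise ValueError("interaction weights must be nonnegative")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal (self-interaction) must be zero")
        if not self.species:
            self.species = [f"sp{i + 1}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class OTEProfile:
    """Row/column totals of an interaction matrix and the outgoing ranking."""

    ote: np.ndarray       # per-species outgoing TE (row sums)
    ite: np.ndarray       # per-species incoming TE (column sums)
    ranking: list[tuple[str, float]]  # descending by OTE

    @property
    def total_interaction(self) -> float:
        return float(self.ote.sum())


def _mi_scan_all_pairs(X: np.ndarray, u_max: int) -> np.ndarray:
    """Gaussian lagged-MI fast path: MI[u, i, j] = I(x_i(t-u); x_j(t)) for all
    ordered pairs at once via truncated-slice correlation matrices."""
    n, L = X.shape
    out = np.empty((u_max + 1, n, n))
    for u in range(u_max + 1):
        A = X[:, : L - u] if u else X
        B = X[:, u:] if u else X
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        sa = np.sqrt((Ac ** 2).sum(axis=1))
        sb = np.sqrt((Bc ** 2).sum(axis=1))
        denom = np.outer(sa, sb)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Ac @ Bc.T) / denom
        r = np.nan_to_num(r)
        r2 = np.clip(r * r, 0.0, 1 - 1e-15)
        out[u] = -0.5 * np.log2(1.0 - r2)
    return out


def infer_matrix(na: NormalizedAbundance | np.ndarray, estimator: str = "gaussian",
                 u_max: int = 10, window_id=None, bins: int = 8,
                 bandwidth: float = 0.5, species: list[str] | None = None,
                 ) -> InteractionMatrix:
    """Infer the raw (unthresholded) TE matrix for a community.

    ``na`` is a NormalizedAbundance or a species x time array.  Subsets shorter
    than 16 points produce a best-effort estimate with a warning (the shortest
    canonical temperature subset has 16 points).
    """
    if isinstance(na, NormalizedAbundance):
        X = na.x
        if species is None and na.species_meta:
            species = [m.scientific_name or f"sp{m.index}" for m in na.species_meta]
    else:
        X = np.asarray(na, dtype=float)
    n, L = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 species to infer interactions, got {n}")
    if L < 16:
        warnings.warn(f"subset of {L} points is short; TE estimates are best-effort")
    u_max_eff = min(u_max, max(L - 8 - 1, 0))
    if u_max_eff < u_max:
        warnings.warn(f"u_max reduced to {u_max_eff} for series of length {L}")

    W = np.zeros((n, n))
    delays = np.zeros((n, n), dtype=int)
    kw = {"bins": bins, "bandwidth": bandwidth}
    if estimator == "gaussian":
        mi = _mi_scan_all_pairs(X, u_max_eff)
        ustar = mi.argmax(axis=0)  # first maximizer -> smallest u on ties
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                te = info.transfer_entropy(X[i], X[j], u=int(ustar[i, j]),
                                           estimator="gaussian")
                W[i, j] = te.value
                delays[i, j] = ustar[i, j]
    else:
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                te, scan = info.te_with_optimal_delay(
                    X[i], X[j], u_max=u_max_eff, estimator=estimator, **kw)
                W[i, j] = te.value
                delays[i, j] = scan.u_star
    return InteractionMatrix(W=W, delays=delays, estimator=estimator,
                             window_id=window_id, species=species or [])


def apply_threshold(im: InteractionMatrix, mode: str = "fixed",
                    value: float | None = None) -> InteractionMatrix:
    """Filter weak links.

    ``fixed``: zero entries below ``value`` (default 0.01 bits).
    ``pareto20``: keep the ceil(0.2 * n(n-1)) largest off-diagonal entries;
    ties at the cutoff are all kept (deterministic, order-independent).
    ``alpha_opt``: ``value`` must carry the threshold from
    :func:`optimize_threshold`.
    ``none``: identity.
    """
    if mode not in THRESHOLD_MODES:
        raise ValueError(f"unknown threshold mode {mode!r}; valid: {THRESHOLD_MODES}")
    W = im.W.copy()
    n = im.n
    if mode == "none":
        thr = 0.0
    elif mode == "fixed":
        thr = 0.01 if value is None else float(value)
    elif mode == "alpha_opt":
        if value is None:
            raise ValueError("alpha_opt mode requires the optimized threshold value")
        thr = float(value)
    else:  # pareto20
        off = W[~np.eye(n, dtype=bool)]
        k = math.ceil(0.2 * n * (n - 1))
        pos = np.sort(off)[::-1]
        thr = float(pos[k - 1]) if k <= pos.size else 0.0
        kept = int((off >= thr).sum()) if thr > 0 else int((off > 0).sum())
        if thr > 0 and kept > k:
            warnings.warn(f"pareto20 ties at cutoff {thr:g}: keeping {kept} > {k} links")
    if thr > 0:
        W[W < thr] = 0.0
    return InteractionMatrix(W=W, delays=im.delays, estimator=im.estimator,
                             threshold=thr, threshold_mode=mode,
                             window_id=im.window_id, species=im.species)


def effective_alpha(im: InteractionMatrix | np.ndarray) -> int:
    """Effective alpha-diversity: the number of species with at least one
    (incoming or outgoing) nonzero link, i.e. connected nodes of the network.
    Absolute values are taken for generality with signed matrices."""
    W = im.W if isinstance(im, InteractionMatrix) else np.asarray(im)
    tot = np.abs(W).sum(axis=0) + np.abs(W).sum(axis=1)
    return int((tot != 0).sum())


def optimize_threshold(W_sequence: list[InteractionMatrix],
                       observed_alpha: np.ndarray,
                       max_candidates: int = 100,
                       objective: str = "rmse") -> float:
    """Grid-search the TE threshold that makes per-window effective diversity
    best predict the observed taxonomic diversity.

    Candidates are the distinct positive weights pooled over windows (or
    ``max_candidates`` quantiles when there are more).  Objective ``rmse``
    minimizes root-mean-square error between effective and observed alpha;
    ``corr`` maximizes their Pearson correlation.  Ties break toward the
    larger threshold (sparser network).
    """
    observed_alpha = np.asarray(observed_alpha, dtype=float)
    if len(W_sequence) < 5:
        raise ValueError("need at least 5 windows to optimize the threshold")
    if len(W_sequence) != observed_alpha.size:
        raise ValueError("one observed alpha value per window is required")
    pooled = np.concatenate([m.W[~np.eye(m.n, dtype=bool)] for m in W_sequence])
    cand = np.unique(pooled[pooled > 0])
    if cand.size == 0:
        warnings.warn("all weights are zero; falling back to fixed 0.01")
        return 0.01
    if cand.size > max_candidates:
        cand = np.unique(np.quantile(cand, np.linspace(0, 1, max_candidates)))
    best_thr, best_score = None, None
    for thr in cand:  # ascending; ties prefer the larger threshold
        ae = np.array([effective_alpha(np.where(m.W >= thr, m.W, 0.0))
                       for m in W_sequence], dtype=float)
        if objective == "rmse":
            score = -float(np.sqrt(np.mean((ae - observed_alpha) ** 2)))
        elif objective == "corr":
            score = float(np.corrcoef(ae, observed_alpha)[0, 1]) if ae.std() > 0 else -np.inf
        else:
            raise ValueError("objective must be 'rmse' or 'corr'")
        if best_score is None or score >= best_score:
            best_thr, best_score = float(thr), score
    constant = np.all(observed_alpha == observed_alpha[0])
    if constant and objective == "rmse" and best_score < 0:
        # a constant target no threshold can reach: degenerate problem
        warnings.warn("observed alpha is constant and unreachable; "
                      "falling back to fixed 0.01")
        return 0.01
    return best_thr


def ote_profile(im: InteractionMatrix) -> OTEProfile:
    """Outgoing/incoming TE totals per species and the descending OTE ranking."""
    ote = im.W.sum(axis=1)
    ite = im.W.sum(axis=0)
    order = np.argsort(-ote, kind="stable")
    ranking = [(im.species[i], float(ote[i])) for i in order]
    return OTEProfile(ote=ote, ite=ite, ranking=ranking)


def degree_stats(im: InteractionMatrix) -> pd.DataFrame:
    """Structural, in- and out-degrees of the thresholded network."""
    A = im.W > 0
    out_deg = A.sum(axis=1)
    in_deg = A.sum(axis=0)
    struct = (A | A.T).sum(axis=1)
    return pd.DataFrame({
        "species": im.species,
        "out_degree": out_deg.astype(int),
        "in_degree": in_deg.astype(int),
        "structural_degree": struct.astype(int),
    })


def export_network(im: InteractionMatrix, path: str | Path, fmt: str = "tsv",
                   node_attrs: dict[str, np.ndarray] | None = None) -> Path:
    """Write the network as a weighted directed edge list (TSV: source, target,
    te, delay) or GraphML with optional node attributes (e.g. Shannon entropy,
    OTE)."""
    path = Path(path)
    if fmt == "tsv":
        rows = []
        for i in range(im.n):
            for j in range(im.n):
                if im.W[i, j] > 0:
                    rows.append((im.species[i], im.species[j],
                                 im.W[i, j], int(im.delays[i, j])))
        df = pd.DataFrame(rows, columns=["source", "target", "te", "delay"])
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        for k, name in enumerate(im.species):
            attrs = {a: float(v[k]) for a, v in (node_attrs or {}).items()}
            g.add_node(name, **attrs)
        for i in range(im.n):
            for j in range(im.n):
                if im.W[i, j] > 0:
                    g.add_edge(im.species[i], im.species[j],
                               te=float(im.W[i, j]), delay=int(im.delays[i, j]))
        nx.write_graphml(g, path)
    else:
        raise ValueError("format must be 'tsv' or 'graphml'")
    return path


def import_edge_list(path: str | Path, species: list[str]) -> InteractionMatrix:
    """Round-trip reader for the TSV edge list."""
    df = pd.read_csv(path, sep="\t")
    n = len(species)
    idx = {s: k for k, s in enumerate(species)}
    W = np.zeros((n, n))
    delays = np.zeros((n, n), dtype=int)
    for _, row in df.iterrows():
        i, j = idx[row["source"]], idx[row["target"]]
        W[i, j] = row["te"]
        delays[i, j] = row["delay"]
    return InteractionMatrix(W=W, delays=delays, species=list(species))
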