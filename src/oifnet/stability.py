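"""Eigen-based stability of interaction matrices and sliding-window dynamics.

Per window the pipeline infers a TE matrix, thresholds it, and records the
complex eigenvalue spectrum, the dominant eigenvalue (maximum real part; for a
nonnegative matrix this coincides with the Perron-Frobenius spectral-radius
eigenvalue, which is real), dynamic stability DS = |Re(xi_max)|, total
interaction TI = sum(W), and effective alpha-diversity.  Trajectories of DS and
TI over windows are the critical-slowing-down detection surface: a drifting
community shows trending DS/TI where a stationary one stays flat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .abundance import NormalizedAbundance, TRPartition, WindowSpec
from . import network as net
from . import infodynamics as info

__all__ = [
    "StabilityRecord",
    "eigen_spectrum",
    "total_interaction",
    "sweep",
    "tr_conditional_sweep",
    "temperature_stability_causality",
    "divergence_tracking",
    "trend_test",
]


@dataclass
class StabilityRecord:
    """Per-window eigen spectrum and the derived stability metrics."""

    window_id: object
    axis: str
    eigenvalues: np.ndarray
    dominant: complex
    DS: float
    TI: float
    alpha_e: int
    mean_temp: float = np.nan
    n_points: int = 0
    flags: list[str] = field(default_factory=list)
    matrix: net.InteractionMatrix | None = None


def eigen_spectrum(W: np.ndarray) -> tuple[np.ndarray, complex, int]:
    """Full complex spectrum, the dominant eigenvalue (max real part) and the
    count of eigenvalues with positive real part."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("interaction matrix must be square")
    eig = np.linalg.eigvals(W)
    dominant = eig[np.argmax(eig.real)]
    n_pos = int((eig.real > 0).sum())
    return eig, complex(dominant), n_pos


def total_interaction(W: np.ndarray | net.InteractionMatrix) -> float:
    """TI = sum of all entries of the interaction matrix."""
    W = W.W if isinstance(W, net.InteractionMatrix) else np.asarray(W)
    return float(W.sum())


def _drop_absent(im: net.InteractionMatrix, raw: np.ndarray | None
                 ) -> tuple[net.InteractionMatrix, list[str]]:
    """Species absent from a subset (all raw counts zero) are removed before
    eigen-analysis, shrinking the effective matrix dimension."""
    if raw is None:
        return im, []
    present = raw.sum(axis=1) > 0
    if present.all():
        return im, []
    keep = np.nonzero(present)[0]
    sub = net.InteractionMatrix(
        W=im.W[np.ix_(keep, keep)], delays=im.delays[np.ix_(keep, keep)],
        estimator=im.estimator, threshold=im.threshold,
        threshold_mode=im.threshold_mode, window_id=im.window_id,
        species=[im.species[k] for k in keep])
    dropped = [im.species[k] for k in np.nonzero(~present)[0]]
    return sub, dropped


def record_from_matrix(im: net.InteractionMatrix, axis: str,
                       mean_temp: float = np.nan, n_points: int = 0,
                       raw: np.ndarray | None = None,
                       keep_matrix: bool = False) -> StabilityRecord:
    sub, dropped = _drop_absent(im, raw)
    eig, dom, _ = eigen_spectrum(sub.W)
    rec = StabilityRecord(
        window_id=im.window_id, axis=axis, eigenvalues=eig, dominant=dom,
        DS=abs(dom.real), TI=total_interaction(im), alpha_e=net.effective_alpha(im),
        mean_temp=mean_temp, n_points=n_points,
        matrix=im if keep_matrix else None)
    if dropped:
        rec.flags.append(f"dropped_absent:{','.join(dropped)}")
    return rec


def sweep(na: NormalizedAbundance, spec: WindowSpec, estimator: str = "gaussian",
          u_max: int = 10, threshold_mode: str = "fixed",
          threshold_value: float | None = None, min_points: int = 16,
          keep_matrices: bool = False, binarize: bool = False,
          ) -> list[StabilityRecord]:
    """Infer, threshold and eigen-analyze one network per window.

    Windows along ``time`` slice census points; along ``temperature`` they
    select the census points whose mean temperature falls in each half-open
    [T, T+width) interval (time order preserved).  Windows shorter than
    ``min_points`` are flagged, not dropped.  ``binarize`` replaces weights by
    0/1 adjacency before eigen-analysis (the structural variant tracked in
    parallel with the weighted one).
    """
    records = []
    if spec.axis == "time":
        selections = [np.arange(sl.start, min(sl.stop, na.L))
                      for sl in spec.time_slices()]
        ids = list(spec.starts())
    else:
        T = na.mean_temp
        selections, ids = [], []
        for lo, hi in spec.temperature_intervals():
            selections.append(np.nonzero((T >= lo) & (T < hi))[0])
            ids.append(lo)
    for g, idx in zip(ids, selections):
        sub = na.subset(np.asarray(idx))
        flags = []
        if sub.L < min_points:
            flags.append(f"short_window:{sub.L}")
        if sub.L < 10:
            # too short for any estimate: empty record
            rec = StabilityRecord(window_id=g, axis=spec.axis,
                                  eigenvalues=np.array([]), dominant=0j,
                                  DS=np.nan, TI=np.nan, alpha_e=0,
                                  mean_temp=float(np.mean(sub.mean_temp)) if sub.L else np.nan,
                                  n_points=sub.L, flags=flags + ["empty"])
            records.append(rec)
            continue
        # cap the delay scan by the window length: scanning many lags on a
        # short window both wastes sample and inflates the max-selection
        # noise floor of the TE estimates
        u_eff = min(u_max, max(sub.L // 8, 1))
        with warnings.catch_warnings():
            # species constant within a window carry no information; the
            # gaussian estimator returns TE 0 for them without complaint
            warnings.simplefilter("ignore")
            im = net.infer_matrix(sub.x, estimator=estimator, u_max=u_eff, window_id=g)
            im = net.apply_threshold(im, mode=threshold_mode, value=threshold_value)
        if binarize:
            im = net.InteractionMatrix(W=(im.W > 0).astype(float), delays=im.delays,
                                       estimator=im.estimator, threshold=im.threshold,
                                       threshold_mode=im.threshold_mode,
                                       window_id=g, species=im.species)
        rec = record_from_matrix(im, axis=spec.axis,
                                 mean_temp=float(np.mean(sub.mean_temp)),
                                 n_points=sub.L, raw=sub.raw_counts,
                                 keep_matrix=keep_matrices)
        rec.flags.extend(flags)
        records.append(rec)
    return records


def tr_conditional_sweep(partition: TRPartition, spec_l: int = 24,
                         spec_step: int = 2, **kw) -> dict[str, list[StabilityRecord]]:
    """Time-windowed stability records within each temperature-range subset.

    Subsets too short for even one window yield a flagged empty sequence
    (the coldest canonical subset has only 16 points)."""
    out = {}
    for label, sub in zip(partition.bins, partition.subsets):
        if sub.L < 10:
            warnings.warn(f"TR {label}: only {sub.L} points; no windows")
            out[label] = []
            continue
        l_eff = min(spec_l, sub.L)
        spec = WindowSpec(axis="time", L=sub.L, l=l_eff, step=spec_step)
        out[label] = sweep(sub, spec, **kw)
    return out


def temperature_stability_causality(partition: TRPartition,
                                    records: dict[str, list[StabilityRecord]],
                                    u_max: int = 10, estimator: str = "gaussian",
                                    ) -> dict[str, float]:
    """TE(temperature -> Re(dominant eigenvalue)) per temperature range.

    The per-window mean temperature and the per-window Re(xi_max) series form
    the two aligned inputs."""
    out = {}
    for label in partition.bins:
        recs = records.get(label, [])
        temp = np.array([r.mean_temp for r in recs])
        dom = np.array([r.dominant.real for r in recs])
        ok = np.isfinite(temp) & np.isfinite(dom)
        if ok.sum() < 20:
            out[label] = np.nan
            continue
        u_eff = min(u_max, int(ok.sum()) - 9)
        res = info.te_from_temperature(temp[ok], dom[ok], u_max=max(u_eff, 0),
                                       estimator=estimator)
        out[label] = res["forward"].value
    return out


def divergence_tracking(records: list[StabilityRecord], roles: list[str],
                        bins: int = 20, smoothing: float = 1e-6
                        ) -> dict[str, np.ndarray]:
    """Competitive-vs-cooperative divergence per window.

    For each record (which must carry its matrix, ``keep_matrices=True`` in
    :func:`sweep`): the dominant eigenvalue of the competitive and cooperative
    submatrices, their difference, and the KL divergence between the two
    groups' positive interaction-weight distributions (equal-width bins over
    the pooled range, additive smoothing).
    """
    roles = list(roles)
    comp = np.array([r == "competitive" for r in roles])
    coop = ~comp
    if comp.sum() == 0 or coop.sum() == 0:
        raise ValueError("both role groups must be non-empty")
    dom_c, dom_o, kl = [], [], []
    for rec in records:
        if rec.matrix is None:
            raise ValueError("records must keep their matrices (keep_matrices=True)")
        W = rec.matrix.W
        _, dc, _ = eigen_spectrum(W[np.ix_(comp, comp)])
        _, do, _ = eigen_spectrum(W[np.ix_(coop, coop)])
        dom_c.append(dc.real)
        dom_o.append(do.real)
        wc = W[comp][:, comp].ravel()
        wo = W[coop][:, coop].ravel()
        pooled = np.concatenate([wc, wo])
        hi = pooled.max() if pooled.max() > 0 else 1.0
        edges = np.linspace(0, hi, bins + 1)
        pc, _ = np.histogram(wc, bins=edges)
        po, _ = np.histogram(wo, bins=edges)
        p = (pc + smoothing) / (pc + smoothing).sum()
        q = (po + smoothing) / (po + smoothing).sum()
        kl.append(float((p * np.log2(p / q)).sum()))
    return {"dominant_competitive": np.array(dom_c),
            "dominant_cooperative": np.array(dom_o),
            "difference": np.array(dom_c) - np.array(dom_o),
            "kl_divergence": np.array(kl)}


def trend_test(series, alternative: str = "increasing") -> dict[str, float]:
    """Mann-Kendall-type monotone-trend test via Kendall's tau against the
    window index (equivalent statistic; a convenience diagnostic rather than a
    claim about any particular published procedure)."""
    y = np.asarray(series, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 4:
        raise ValueError("need at least 4 finite points for a trend test")
    t = np.arange(y.size)
    alt = {"increasing": "greater", "decreasing": "less", "two-sided": "two-sided"}
    if alternative not in alt:
        raise ValueError(f"alternative must be one of {sorted(alt)}")
    res = stats.kendalltau(t, y, alternative=alt[alternative])
    return {"tau": float(res.statistic), "p_value": float(res.pvalue)}
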