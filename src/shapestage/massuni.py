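"""Mass-univariate vertex-wise statistics with searchlight FDR control.

Each vertex's thickness is regressed on a predictor of interest (a group
contrast or a clinical score) with age, sex and intracranial volume as
nuisance covariates and the acquisition cohort as a random intercept
(REML; see :mod:`shapestage.lmm`).  Two-sided Wald p-values are corrected by
a searchlight false-discovery-rate procedure: Benjamini-Hochberg applied
within each vertex's geodesic (edge-hop) neighborhood, a vertex being
significant iff its own p-value passes its neighborhood's BH threshold.
An infinite radius reduces to global BH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ThicknessMatrix
from .errors import AlignmentError, DesignMatrixError, ParameterError
from .graph import adjacency_matrix, hop_neighborhoods
from .lmm import fit_random_intercept
from .mesh import MeshAtlas

__all__ = [
    "DesignSpec",
    "EffectMap",
    "fit_vertex_lmm",
    "map_effects",
    "searchlight_fdr",
    "summarize_map",
]

logger = logging.getLogger(__name__)


@dataclass
class DesignSpec:
    """Vertex-wise regression design.

    ``predictor`` names the column of interest in the covariate table (e.g.
    a 0/1 group indicator, time since diagnosis, MoCA, MDS-UPDRS3);
    ``nuisance`` columns are adjusted for; ``grouping`` is the random
    intercept factor.  ``zscore`` optionally standardizes each vertex's
    thickness before fitting (analysis is in native mm by default).
    """

    predictor: str
    nuisance: tuple[str, ...] = ("age", "sex", "icv")
    grouping: str = "cohort_id"
    zscore: bool = False
    method: str = "profile"  # passed to fit_random_intercept


@dataclass
class EffectMap:
    """Per-vertex regression results for one contrast."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    sig_mask: np.ndarray | None = None
    q_level: float | None = None
    predictor: str = ""

    def __post_init__(self):
        if np.any((self.p < 0) | (self.p > 1)):
            raise ParameterError("p-values must lie in [0, 1]")


def _design_matrix(design: DesignSpec, data: pd.DataFrame):
    cols = [design.predictor, *design.nuisance]
    sub = data[cols + [design.grouping]]
    mask = sub[cols].notna().all(axis=1).to_numpy()
    sub = sub.loc[mask]
    x_int = sub[design.predictor].to_numpy(float)
    if np.ptp(x_int) == 0:
        raise DesignMatrixError(f"predictor {design.predictor!r} is constant")
    X = np.column_stack(
        [np.ones(len(sub)), x_int]
        + [sub[c].to_numpy(float) for c in design.nuisance]
    )
    return X, sub[design.grouping].to_numpy(), mask


def fit_vertex_lmm(
    y: np.ndarray, design: DesignSpec, data: pd.DataFrame
) -> tuple[float, float, float]:
    """(beta, se, p) of the predictor of interest at one vertex."""
    X, groups, mask = _design_matrix(design, data)
    y = np.asarray(y, dtype=float)[mask]
    if design.zscore:
        sd = y.std(ddof=0)
        if sd > 0:
            y = (y - y.mean()) / sd
    fit = fit_random_intercept(y, X, groups, method=design.method)
    return float(fit.beta[1]), float(fit.se[1]), float(fit.p[1])


def map_effects(
    thickness: ThicknessMatrix, design: DesignSpec, data: pd.DataFrame
) -> EffectMap:
    """Fit the vertex model independently at every vertex.

    Rows with missing predictor/nuisance values are dropped (complete-case,
    per analysis).  Vertices whose fit fails get p = 1 and a logged warning.
    """
    if len(data) != thickness.n_subjects or not np.array_equal(
        thickness.subject_ids, data["subject_id"].to_numpy()
    ):
        raise AlignmentError("thickness rows and covariate table are misaligned")
    X, groups, mask = _design_matrix(design, data)
    Y = thickness.values[mask]
    V = thickness.n_vertices
    beta = np.zeros(V)
    se = np.zeros(V)
    p = np.ones(V)
    n_fail = 0
    for v in range(V):
        y = Y[:, v]
        if design.zscore:
            sd = y.std(ddof=0)
            if sd > 0:
                y = (y - y.mean()) / sd
        try:
            fit = fit_random_intercept(y, X, groups, method=design.method)
            beta[v], se[v], p[v] = fit.beta[1], fit.se[1], fit.p[1]
        except Exception as exc:  # noqa: BLE001 - per-vertex robustness
            n_fail += 1
            logger.warning("vertex %d fit failed: %s", v, exc)
    if n_fail:
        logger.warning("%d/%d vertex fits failed (p set to 1)", n_fail, V)
    return EffectMap(beta, se, p, predictor=design.predictor)


def _bh_threshold(pvals: np.ndarray, q: float) -> float:
    """Benjamini-Hochberg data-dependent threshold; -1 when nothing passes."""
    m = len(pvals)
    ps = np.sort(pvals)
    crit = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(ps <= crit)
    return float(ps[passing[-1]]) if len(passing) else -1.0


def searchlight_fdr(
    p: np.ndarray,
    edges: np.ndarray,
    radius_hops: int | None = 5,
    q: float = 0.05,
) -> np.ndarray:
    """Searchlight FDR significance mask.

    BH at level ``q`` is applied within every vertex's geodesic neighborhood
    (all vertices within ``radius_hops`` edge hops, itself included); the
    vertex is significant iff its own p-value is at or below its
    neighborhood's BH threshold.  ``radius_hops=None`` (infinite radius)
    reduces to global BH.  A vertex isolated at radius 0 degenerates to the
    single-test rule p <= q.
    """
    p = np.asarray(p, dtype=float)
    if not (0 < q < 1):
        raise ParameterError("q must be in (0, 1)")
    n = len(p)
    if radius_hops is None:
        thr = _bh_threshold(p, q)
        return p <= thr if thr >= 0 else np.zeros(n, dtype=bool)
    if radius_hops < 0:
        raise ParameterError("radius_hops must be >= 0 or None")
    adj = adjacency_matrix(np.asarray(edges, dtype=np.int64), n)
    hoods = hop_neighborhoods(adj, radius_hops)
    mask = np.zeros(n, dtype=bool)
    for v in range(n):
        thr = _bh_threshold(p[hoods[v]], q)
        mask[v] = thr >= 0 and p[v] <= thr
    return mask


def summarize_map(m: EffectMap, atlas: MeshAtlas) -> pd.DataFrame:
    """Per-structure (% significant vertices, peak beta among significant).

    Peak beta is the signed coefficient of maximal magnitude among the
    structure's significant vertices (0 when none are significant).
    """
    if len(m.beta) != atlas.n_vertices:
        raise AlignmentError("effect map length does not match atlas")
    if m.sig_mask is None:
        raise ParameterError("effect map has no significance mask; run FDR first")
    rows = []
    for key in atlas.structure_keys:
        sl = atlas.structure_slice(key)
        sig = m.sig_mask[sl]
        beta = m.beta[sl]
        pct = 100.0 * sig.sum() / len(sig)
        peak = float(beta[sig][np.argmax(np.abs(beta[sig]))]) if sig.any() else 0.0
        rows.append((key, pct, peak))
    return pd.DataFrame(rows, columns=["structure", "pct_significant", "peak_beta"])
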