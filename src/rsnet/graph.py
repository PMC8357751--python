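"""Weighted graph metrics: clustering coefficient, path length, small-world index.

Networks are weighted, undirected and fully dense (no binary threshold):
every wPLI value is an edge weight.  The weighted clustering coefficient
uses the geometric-mean (Onnela) triangle formula with weights scaled by
the maximum weight; path lengths use the inverse-weight length map
(strong connections are short).  The small-world index is the ratio of
cross-band-normalized clustering to cross-band-normalized path length:
each subject's value in a (condition, band) cell is divided by the mean
of all their other cells, so metrics hover near 1 and condition effects
appear as departures from 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .connectivity import ConnectivityStack


def _check_graph(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if (w < 0).any():
        raise ValueError("negative edge weights are not allowed")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    return w


def clustering_coefficient(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted clustering per node and its unweighted global mean.

    Node i scores sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) / (k_i (k_i - 1)),
    with w' = w / max(w) and k_i the number of nonzero-weight neighbors;
    nodes with fewer than two neighbors score 0.
    """
    w = _check_graph(w)
    n = w.shape[0]
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n), 0.0
    cube = np.cbrt(w / wmax)
    # diagonal of cube^3 counts ordered pairs (j, h) of triangle partners
    triangles = np.diag(cube @ cube @ cube)
    k = (w > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_node = np.where(denom > 0, triangles / denom, 0.0)
    return per_node, float(per_node.mean())


def characteristic_path_length(w: np.ndarray) -> float:
    """Mean shortest-path distance over ordered node pairs.

    Edge length is 1 / weight (infinite for absent edges).  Unreachable
    pairs are excluded with a warning rather than failing.
    """
    w = _check_graph(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(lengths, 0.0)
    # Floyd-Warshall, vectorized over rows; exact for nonnegative lengths
    # and cheap at EEG-montage sizes (n <= 65)
    dist = lengths.copy()
    for mid in range(n):
        np.minimum(dist, dist[:, mid, None] + dist[None, mid, :], out=dist)
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    finite = np.isfinite(d)
    if not finite.all():
        warnings.warn(
            f"{(~finite).sum()} unreachable node pairs excluded from PL",
            RuntimeWarning, stacklevel=2,
        )
    if not finite.any():
        raise ValueError("graph has no connected node pairs")
    return float(d[finite].mean())


def small_world_index(w: np.ndarray) -> float:
    """Raw CC / PL ratio of a single graph (not cross-band normalized)."""
    _, cc = clustering_coefficient(w)
    pl = characteristic_path_length(w)
    return cc / pl


def aggregate_epochs(stack: ConnectivityStack, metric: str,
                     mode: str = "epoch-mean") -> dict[str, float]:
    """Per-band raw graph metric from an epoch-wise connectivity stack.

    metric is one of "cc", "pl", "swi".  mode="epoch-mean" (default)
    computes the metric on each epoch's matrix and averages; the
    "mean-matrix" alternative averages the matrices first.
    """
    if stack.n_epochs == 0:
        raise ValueError("empty connectivity stack")
    funcs = {
        "cc": lambda w: clustering_coefficient(w)[1],
        "pl": characteristic_path_length,
        "swi": small_world_index,
    }
    if metric not in funcs:
        raise ValueError(f"unknown metric {metric!r}")
    f = funcs[metric]
    out: dict[str, float] = {}
    for bi, band in enumerate(stack.bands):
        if mode == "epoch-mean":
            vals = [f(stack.data[bi, ei]) for ei in range(stack.n_epochs)]
            out[band.name] = float(np.mean(vals))
        elif mode == "mean-matrix":
            out[band.name] = float(f(stack.data[bi].mean(axis=0)))
        else:
            raise ValueError("mode must be 'epoch-mean' or 'mean-matrix'")
    return out


def metrics_from_stack(stack: ConnectivityStack,
                       mode: str = "epoch-mean") -> pd.DataFrame:
    """Tidy raw metric rows (subject, condition, band, cc_raw, pl_raw)."""
    cc = aggregate_epochs(stack, "cc", mode)
    pl = aggregate_epochs(stack, "pl", mode)
    subj = stack.provenance.get("subject_id", "")
    cond = stack.provenance.get("condition", "")
    return pd.DataFrame([
        {"subject": subj, "condition": cond, "band": b,
         "cc_raw": cc[b], "pl_raw": pl[b]}
        for b in (band.name for band in stack.bands)
    ])


def _loo_normalize(values: np.ndarray, include_self: bool) -> np.ndarray:
    """Divide each cell by the mean of the other cells (or of all cells)."""
    n = values.size
    total = values.sum()
    if include_self:
        denom = np.full(n, total / n)
    else:
        if n < 2:
            raise ValueError("leave-one-out normalization needs >= 2 cells")
        denom = (total - values) / (n - 1)
    if np.any(denom <= 0):
        raise ValueError("normalization denominator is not positive")
    return values / denom


def normalize_metrics(raw: pd.DataFrame, scope: str = "conditions-bands",
                      include_self: bool = False) -> pd.DataFrame:
    """Cross-band normalization and small-world index per subject.

    Each subject's raw CC (and PL) value in a (condition, band) cell is
    divided by the mean of all their *other* cells; SWI is the cellwise
    ratio of normalized CC to normalized PL.  scope="conditions-bands"
    (default) pools the normalization cells over conditions and bands;
    scope="bands" normalizes within each condition across bands only.
    The full condition x band grid must be present per subject.
    """
    required = {"subject", "condition", "band", "cc_raw", "pl_raw"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw table lacks columns {sorted(missing)}")
    conditions = list(dict.fromkeys(raw["condition"]))
    bands = list(dict.fromkeys(raw["band"]))

    out_rows = []
    for subject, grp in raw.groupby("subject", sort=False):
        cells = grp.set_index(["condition", "band"])
        expected = [(c, b) for c in conditions for b in bands]
        gaps = [cb for cb in expected if cb not in cells.index]
        if gaps:
            raise ValueError(f"subject {subject}: missing cells {gaps}")
        cells = cells.loc[expected]
        for metric in ("cc", "pl"):
            vals = cells[f"{metric}_raw"].to_numpy(dtype=float)
            if scope == "conditions-bands":
                norm = _loo_normalize(vals, include_self)
            elif scope == "bands":
                norm = np.empty_like(vals)
                grid = vals.reshape(len(conditions), len(bands))
                for ci in range(len(conditions)):
                    norm.reshape(len(conditions), len(bands))[ci] = \
                        _loo_normalize(grid[ci], include_self)
            else:
                raise ValueError("scope must be 'conditions-bands' or 'bands'")
            cells[f"{metric}_norm"] = norm
        cells["swi"] = cells["cc_norm"] / cells["pl_norm"]
        cells["subject"] = subject
        out_rows.append(cells.reset_index())
    out = pd.concat(out_rows, ignore_index=True)
    return out[["subject", "condition", "band",
                "cc_raw", "pl_raw", "cc_norm", "pl_norm", "swi"]]
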