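"""Regional N-surplus typologies via a small self-organizing map.

Regions are classified into four archetypes — MAN (manure-dominated),
FERT (fertilizer-dominated), MOD (moderate mixed) and NAT (natural
landscapes) — from the centennial shape of their nitrogen budgets.  The
feature vector of a region is the decadal mean (1850s…2010s, 17 decades)
of twelve variables: the two fertilizer-input data variants, the four
manure-input variants, fixation, deposition, the two output variants
(pasture-removal datasets) and the agricultural and non-agricultural
areas.  Columns are z-scored; flux variables enter on the
per-total-area mass basis so agricultural and natural regions are
directly comparable.

Clustering uses a 2 x 2 Kohonen map trained in deterministic blended-batch
mode: each epoch assigns every region to its best-matching unit (BMU),
forms Gaussian-neighborhood-weighted batch targets and moves the node
weights a decaying learning-rate step toward them.  Batch updates make the
partition invariant to region order.  Cluster-count selection is
diagnosed with the Davies–Bouldin index (lower = better separated), and
nodes are turned into labels by an explicit rule on agricultural-area
fraction and input shares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from .budget import INPUT_COMPONENTS, member_mean
from . import budget

logger = logging.getLogger(__name__)

DECADES = tuple(range(1850, 2020, 10))  # 17 decade starts
LABELS = ("MAN", "FERT", "MOD", "NAT")

#: SOM training defaults
DEFAULT_EPOCHS = 500
DEFAULT_RADIUS = (1.0, 0.1)
DEFAULT_LEARNING_RATE = (0.5, 0.01)


@dataclass
class FeatureMatrix:
    """z-scored region x (variable, decade) design matrix."""

    X: np.ndarray
    region_ids: list[str]
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str]

    @property
    def n_regions(self) -> int:
        return self.X.shape[0]


@dataclass
class SOMGrid:
    """Trained map: node lattice coordinates and weight vectors."""

    shape: tuple[int, int]
    grid: np.ndarray      # (k, 2) lattice coordinates
    weights: np.ndarray   # (k, p)
    epochs: int
    radius: tuple[float, float]
    learning_rate: tuple[float, float]
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _variant_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Per (region, year): the 12 classification variables.

    Ensemble data variants are separate variables: fertilizer input per
    fertilizer variant (2), manure input per manure variant (4), total
    output per pasture variant (2); deposition and fixation are variant-
    free and averaged over members.  Fluxes are converted to the
    per-total-area basis before averaging so regions with small
    agricultural fractions are not inflated.
    """
    members = budget.ensemble_members()
    rec = records.merge(members, on="member_id", how="left")
    if rec[["fert_variant"]].isna().any().any():
        raise ValueError("member_id outside the 16-member ensemble enumeration")

    total = budget.combine_sectors(rec)
    total = total.merge(members, on="member_id", how="left")
    total["out_total"] = total["out_crops"] + total["out_past"]

    key = ["region_id", "year"]
    pieces = []
    for v in (1, 2):
        s = total[total["fert_variant"] == v].groupby(key)["in_fert"].mean()
        pieces.append(s.rename(f"fert{v}"))
    for v in (1, 2, 3, 4):
        s = total[total["manure_variant"] == v].groupby(key)["in_man"].mean()
        pieces.append(s.rename(f"man{v}"))
    pieces.append(total.groupby(key)["in_bnf"].mean().rename("bnf"))
    pieces.append(total.groupby(key)["in_dep"].mean().rename("dep"))
    for v in (1, 2):
        s = total[total["pasture_variant"] == v].groupby(key)["out_total"].mean()
        pieces.append(s.rename(f"out{v}"))
    pieces.append(total.groupby(key)["ag_area"].mean().rename("ag_area"))
    pieces.append(total.groupby(key)["nonag_area"].mean().rename("nonag_area"))
    return pd.concat(pieces, axis=1).reset_index()


def build_features(
    records: pd.DataFrame,
    decades: Sequence[int] = DECADES,
    collapse_decades: bool = False,
) -> FeatureMatrix:
    """Decadal-mean feature matrix, z-scored per column.

    Each variable contributes one column per decade (default) or a single
    centennial mean when ``collapse_decades`` is set.  Columns with zero
    variance are dropped with a warning.  z-scoring uses the population
    standard deviation.
    """
    var = _variant_columns(records)
    var["decade"] = (var["year"] // 10) * 10
    var = var[var["decade"].isin(decades)]
    if sorted(var["decade"].unique()) != sorted(decades):
        missing = set(decades) - set(var["decade"].unique())
        raise ValueError(f"records do not cover decades {sorted(missing)}")
    value_cols = [c for c in var.columns if c not in ("region_id", "year", "decade")]
    dec = var.groupby(["region_id", "decade"], sort=True)[value_cols].mean()
    if collapse_decades:
        wide = dec.groupby("region_id").mean()
        wide.columns = [f"{c}_centennial" for c in wide.columns]
    else:
        wide = dec.unstack("decade")
        wide.columns = [f"{v}_{d}s" for v, d in wide.columns]
    if wide.isna().any().any():
        raise ValueError("incomplete decadal coverage for some regions")

    X = wide.to_numpy(float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    # constant up to float round-off counts as constant
    keep = sds > 1e-12 * np.maximum(np.abs(means), 1.0)
    dropped = [c for c, k in zip(wide.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature columns", stacklevel=2)
    Xz = (X[:, keep] - means[keep]) / sds[keep]
    return FeatureMatrix(
        X=Xz,
        region_ids=list(wide.index),
        columns=[c for c, k in zip(wide.columns, keep) if k],
        means=means[keep],
        sds=sds[keep],
        dropped=dropped,
    )


def _pca_init(X: np.ndarray, grid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Spread initial node weights on the first principal plane.

    Deterministic: SVD with a sign convention (largest-magnitude loading
    positive).  Falls back to small random jitter around the mean when the
    data have fewer than two informative directions.
    """
    mu = X.mean(axis=0)
    Xc = X - mu
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(min(2, vt.shape[0])):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    scale = s / np.sqrt(max(X.shape[0], 1))
    centered = grid - grid.mean(axis=0)
    span = np.where(np.abs(centered).max(axis=0) > 0, np.abs(centered).max(axis=0), 1.0)
    coords = centered / span  # in [-1, 1]
    w = np.tile(mu, (len(grid), 1))
    for axis in range(2):
        if axis < len(s) and scale[axis] > 0:
            w += np.outer(coords[:, axis] * scale[axis], vt[axis])
        else:
            w += rng.normal(0.0, 1e-6, size=w.shape)
    return w


def train_som(
    features: FeatureMatrix | np.ndarray,
    shape: tuple[int, int] = (2, 2),
    epochs: int = DEFAULT_EPOCHS,
    radius: tuple[float, float] = DEFAULT_RADIUS,
    learning_rate: tuple[float, float] = DEFAULT_LEARNING_RATE,
    seed: int = 0,
) -> SOMGrid:
    """Train a rectangular-lattice SOM in blended-batch mode.

    Each epoch: (1) BMU assignment of all samples, (2) Gaussian-
    neighborhood weighted batch target per node, (3) weight step
    ``w += lr * (target - w)`` with radius and learning rate decaying
    geometrically from their initial to final values.  Fixed inputs and
    seed give identical weights; sample order never enters.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n, p = X.shape
    k = shape[0] * shape[1]
    if n < k:
        raise ValueError(f"need at least {k} samples for a {shape} map, got {n}")
    rng = np.random.default_rng(seed)
    grid = np.array([(i, j) for i in range(shape[0]) for j in range(shape[1])], float)
    d2_grid = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)
    w = _pca_init(X, grid, rng)

    r0, r1 = radius
    a0, a1 = learning_rate
    for t in range(epochs):
        frac = t / max(epochs - 1, 1)
        sigma = r0 * (r1 / r0) ** frac if r0 > 0 and r1 > 0 else r0 * (1 - frac) + r1 * frac
        alpha = a0 * (a1 / a0) ** frac if a0 > 0 and a1 > 0 else a0 * (1 - frac) + a1 * frac
        if alpha == 0.0:
            continue
        bmu = _assign(X, w)
        if sigma <= 0:
            h = np.eye(k)
        else:
            h = np.exp(-d2_grid / (2.0 * sigma * sigma))
        hw = h[:, bmu]                      # (k, n) neighborhood weight per sample
        denom = hw.sum(axis=1)
        target = np.where(denom[:, None] > 0, hw @ X / np.where(denom == 0, 1, denom)[:, None], w)
        w = w + alpha * (target - w)

    som = SOMGrid(shape=shape, grid=grid, weights=w, epochs=epochs,
                  radius=radius, learning_rate=learning_rate, seed=seed)
    occupied = np.bincount(_assign(X, w), minlength=k)
    for node, cnt in enumerate(occupied):
        if cnt == 0:
            warnings.warn(f"SOM node {node} is empty at convergence", stacklevel=2)
    return som


def _assign(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def assign(som: SOMGrid, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Best-matching node (Euclidean) per region."""
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    return _assign(X, som.weights)


def davies_bouldin(features: FeatureMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Davies–Bouldin index: mean over clusters of max_j (S_i+S_j)/M_ij.

    S is the mean Euclidean distance to the centroid, M the centroid
    distance.  Identical centroids make the ratio undefined and raise.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 non-empty clusters")
    centroids = np.array([X[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [np.linalg.norm(X[labels == u] - centroids[i], axis=1).mean()
         for i, u in enumerate(uniq)]
    )
    M = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    off_diag = ~np.eye(k, dtype=bool)
    if np.any(M[off_diag] == 0):
        raise ValueError("identical cluster centroids: Davies-Bouldin undefined")
    with np.errstate(divide="ignore"):
        R = (scatter[:, None] + scatter[None, :]) / np.where(off_diag, M, np.inf)
    return float(np.max(np.where(off_diag, R, -np.inf), axis=1).mean())


def select_k(
    features: FeatureMatrix | np.ndarray,
    k_candidates: Sequence[int] = range(2, 7),
    seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
) -> pd.DataFrame:
    """Davies–Bouldin diagnostics over candidate node counts.

    k=4 uses the 2x2 lattice; other k use a 1xk chain.  The minimum is
    flagged, not auto-adopted.  Candidates larger than the sample count
    are skipped with a warning; degenerate solutions get DBI = NaN.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    rows = []
    for k in k_candidates:
        if k > X.shape[0]:
            warnings.warn(f"skipping k={k}: only {X.shape[0]} regions", stacklevel=2)
            continue
        shape = (2, 2) if k == 4 else (1, k)
        som = train_som(X, shape=shape, epochs=epochs, seed=seed)
        nodes = assign(som, X)
        try:
            dbi = davies_bouldin(X, nodes)
        except ValueError:
            dbi = np.nan
        rows.append({"k": k, "shape": f"{shape[0]}x{shape[1]}",
                     "n_occupied": len(np.unique(nodes)), "dbi": dbi})
    out = pd.DataFrame(rows)
    if out["dbi"].notna().any():
        out["is_minimum"] = out["dbi"] == out["dbi"].min()
    else:
        out["is_minimum"] = True  # degenerate: every candidate flagged
    return out


def label_typologies(
    node_of_region: pd.Series,
    records: pd.DataFrame,
) -> tuple[dict[int, str], pd.DataFrame]:
    """Rule-based node -> {MAN, FERT, MOD, NAT} labelling.

    The node with the lowest mean agricultural-area fraction is NAT; among
    the rest, highest centennial manure share of inputs is MAN, then
    highest fertilizer share is FERT, the remainder MOD.  Ties on the
    share rules are broken by surplus magnitude (highest -> MAN).  A node
    count other than four, or an unresolvable tie, raises with diagnostics.
    """
    nodes = sorted(node_of_region.unique())
    if len(nodes) != 4:
        raise ValueError(f"labelling rule needs exactly 4 clusters, got {len(nodes)}")

    mm = member_mean(records[records["sector"] == "agricultural"])
    per_region = mm.groupby("region_id").agg(
        ag_area=("ag_area", "mean"), nonag_area=("nonag_area", "mean"),
        in_fert=("in_fert", "mean"), in_man=("in_man", "mean"),
        in_dep=("in_dep", "mean"), in_bnf=("in_bnf", "mean"),
        out_crops=("out_crops", "mean"), out_past=("out_past", "mean"),
    )
    per_region["ag_fraction"] = per_region["ag_area"] / (
        per_region["ag_area"] + per_region["nonag_area"]
    )
    total_in = per_region[INPUT_COMPONENTS].sum(axis=1)
    per_region["man_share"] = per_region["in_man"] / total_in
    per_region["fert_share"] = per_region["in_fert"] / total_in
    per_region["surplus"] = total_in - per_region[["out_crops", "out_past"]].sum(axis=1)
    per_region["node"] = node_of_region.reindex(per_region.index)
    if per_region["node"].isna().any():
        missing = per_region.index[per_region["node"].isna()].tolist()
        raise ValueError(f"regions without node assignment: {missing[:10]}")

    stats = per_region.groupby("node")[
        ["ag_fraction", "man_share", "fert_share", "surplus"]
    ].mean()

    labels: dict[int, str] = {}
    nat = stats["ag_fraction"].idxmin()
    labels[nat] = "NAT"
    rest = stats.drop(index=nat)

    def pick(frame: pd.DataFrame, share: str) -> int:
        best = frame[share].max()
        winners = frame.index[frame[share] == best]
        if len(winners) > 1:
            winners = frame.loc[winners, "surplus"].sort_values(ascending=False).index
            if frame.loc[winners[0], "surplus"] == frame.loc[winners[1], "surplus"]:
                raise ValueError(
                    f"labelling tie on {share} unresolved by surplus:\n{frame}"
                )
        return winners[0]

    man = pick(rest, "man_share")
    labels[man] = "MAN"
    rest = rest.drop(index=man)
    fert = pick(rest, "fert_share")
    labels[fert] = "FERT"
    rest = rest.drop(index=fert)
    labels[rest.index[0]] = "MOD"

    diag = stats.copy()
    diag["label"] = [labels[n] for n in stats.index]
    logger.info("typology labelling diagnostics:\n%s", diag)
    return labels, diag


def classify_regions(
    records: pd.DataFrame,
    seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
    collapse_decades: bool = False,
    decades: Sequence[int] = DECADES,
) -> pd.DataFrame:
    """Full pipeline: features -> 2x2 SOM -> node labels -> assignment table.

    Returns a frame with region_id, node and typology label.
    """
    features = build_features(records, decades=decades, collapse_decades=collapse_decades)
    som = train_som(features, shape=(2, 2), epochs=epochs, seed=seed)
    nodes = assign(som, features)
    node_of_region = pd.Series(nodes, index=pd.Index(features.region_ids, name="region_id"))
    labels, _ = label_typologies(node_of_region, records)
    return pd.DataFrame(
        {
            "region_id": features.region_ids,
            "node": nodes,
            "label": [labels[n] for n in nodes],
        }
    )
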