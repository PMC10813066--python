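"""Factor Analysis of Mixed Data (FAMD) with iterative missing-data imputation.

FAMD jointly embeds continuous and categorical variables: continuous columns
are standardized to unit variance (population denominator, as in the French
factorial-analysis tradition); each categorical level's indicator column is
divided by the square root of the level proportion and centered.  The SVD of
the combined matrix yields eigenvalues whose sum equals the total inertia

    p_continuous + Σ_j (levels_j − 1),

with principal-component analysis and multiple correspondence analysis as
the all-continuous and all-categorical limits.

Missing cells are filled by the simple iterative-FAMD scheme: initialize at
the column mean/mode, then alternate (fit on the completed table → low-rank
reconstruction → update the missing cells) until stationarity.  This is a
deterministic, unregularized reduction of regularized iterative FAMD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FAMDModel:
    eigenvalues: np.ndarray           # non-increasing, >= 0
    pct_variance: np.ndarray          # percent of total inertia per axis
    row_coords: np.ndarray            # (n, k) principal coordinates
    col_coords: pd.DataFrame          # per continuous variable / categorical level
    row_cos2: np.ndarray              # squared cosine quality per row x axis
    total_inertia: float
    continuous: tuple[str, ...]
    categorical: tuple[str, ...]


def split_roles(table: pd.DataFrame, categorical: list[str] | None = None):
    """Infer (continuous, categorical) column lists unless given explicitly."""
    if categorical is None:
        categorical = [
            c for c in table.columns
            if not pd.api.types.is_numeric_dtype(table[c]) or pd.api.types.is_bool_dtype(table[c])
        ]
    continuous = [c for c in table.columns if c not in categorical]
    return continuous, list(categorical)


def filter_variables(table: pd.DataFrame, categorical: list[str] | None = None) -> pd.DataFrame:
    """Drop categorical columns with no or almost no variability.

    A column goes when it has fewer than two observed levels, or when some
    level is carried by exactly one record (one presence or one absence
    contributes no stable structure, only leverage).
    """
    _, cat = split_roles(table, categorical)
    drop = []
    for c in cat:
        counts = table[c].dropna().astype(str).value_counts()
        if len(counts) < 2 or counts.min() == 1:
            drop.append(c)
    out = table.drop(columns=drop)
    if out.shape[1] == 0:
        raise ValueError("variability filter removed every variable")
    return out


def _encode(table: pd.DataFrame, continuous, categorical):
    """Build the standardized FAMD matrix Z and column bookkeeping."""
    n = len(table)
    blocks, names, kinds = [], [], []
    for c in continuous:
        x = table[c].to_numpy(dtype=float)
        sd = x.std()  # population sd
        if sd == 0:
            raise ValueError(f"zero-variance continuous column {c!r}")
        blocks.append(((x - x.mean()) / sd)[:, None])
        names.append(c)
        kinds.append("continuous")
    for c in categorical:
        levels = sorted(table[c].astype(str).unique())
        ind = np.column_stack([(table[c].astype(str) == lv).to_numpy(float) for lv in levels])
        p = ind.mean(axis=0)
        z = ind / np.sqrt(p) - np.sqrt(p)
        blocks.append(z)
        names.extend(f"{c}={lv}" for lv in levels)
        kinds.extend(["level"] * len(levels))
    Z = np.hstack(blocks)
    return Z, names, kinds


def fit_famd(
    table: pd.DataFrame,
    n_axes: int = 3,
    categorical: list[str] | None = None,
) -> FAMDModel:
    """Fit FAMD on a complete mixed table.

    Eigenvalues are the squared singular values of Z/√n; row coordinates are
    the principal coordinates ZV; column coordinates are the loadings scaled
    by the singular values (correlations, for continuous variables).
    """
    if table.isna().any().any():
        raise ValueError("table has missing cells; impute first")
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    continuous, categorical = split_roles(table, categorical)
    Z, names, kinds = _encode(table, continuous, categorical)
    n = len(table)
    U, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    eig = s**2
    total = float(len(continuous) + sum(table[c].astype(str).nunique() - 1 for c in categorical))
    k = min(n_axes, (eig > 1e-12).sum())
    row = Z @ Vt[:k].T
    d2 = (Z**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2 = np.where(d2[:, None] > 0, row**2 / d2[:, None], 0.0)
    col = pd.DataFrame(
        (Vt[:k] * s[:k, None]).T,
        index=names,
        columns=[f"axis{i + 1}" for i in range(k)],
    )
    col["kind"] = kinds
    return FAMDModel(
        eigenvalues=eig,
        pct_variance=100 * eig / total,
        row_coords=row,
        col_coords=col,
        row_cos2=cos2,
        total_inertia=total,
        continuous=tuple(continuous),
        categorical=tuple(categorical),
    )


def impute_missing(
    table: pd.DataFrame,
    n_components: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Fill missing cells by iterative FAMD reconstruction; deterministic.

    Continuous cells start at the column mean, categorical cells at the mode;
    each sweep refits the factorial model on the completed table, rebuilds the
    rank-``n_components`` reconstruction and rewrites the missing cells only.
    Stops when the largest cell change drops below ``tol`` (continuous scale) —
    non-convergence at ``max_iter`` warns and returns the last iterate.
    Observed cells are never altered; imputed categorical cells are observed
    levels of their column.
    """
    miss = table.isna()
    if not miss.any().any():
        return table.copy()
    if miss.to_numpy().mean() >= 0.3:
        raise ValueError("more than 30% missing cells; imputation unreliable")
    continuous, categorical = split_roles(table, categorical)
    work = table.copy()
    for c in continuous:
        work[c] = work[c].fillna(table[c].mean())
    for c in categorical:
        mode = table[c].dropna().astype(str).mode()
        work[c] = work[c].astype(object).where(~miss[c], mode.iloc[0]).astype(str)

    # fuzzy indicator weights for missing categorical cells
    fuzzy: dict[str, np.ndarray] = {}
    levels_of = {c: sorted(table[c].dropna().astype(str).unique()) for c in categorical}

    prev = None
    for iteration in range(max_iter):
        n = len(work)
        Z, names, _ = _encode(work, continuous, categorical)
        # overwrite rows of missing categorical cells with fuzzy weights
        offset = len(continuous)
        for c in categorical:
            lvs = sorted(work[c].astype(str).unique())
            if c in fuzzy:
                p = np.array([(work[c].astype(str) == lv).mean() for lv in lvs])
                rows = np.nonzero(miss[c].to_numpy())[0]
                for r, w in zip(rows, fuzzy[c]):
                    Z[r, offset:offset + len(lvs)] = w / np.sqrt(p) - np.sqrt(p)
            offset += len(lvs)
        U, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
        k = min(n_components, len(s))
        Zhat = (U[:, :k] * s[:k]) @ Vt[:k] * np.sqrt(n)

        delta = 0.0
        j = 0
        for c in continuous:
            mu, sd = work[c].mean(), work[c].std(ddof=0)
            rows = np.nonzero(miss[c].to_numpy())[0]
            for r in rows:
                new = Zhat[r, j] * sd + mu
                delta = max(delta, abs(new - work.at[work.index[r], c]))
                work.at[work.index[r], c] = new
            j += 1
        for c in categorical:
            lvs = sorted(work[c].astype(str).unique())
            p = np.array([(work[c].astype(str) == lv).mean() for lv in lvs])
            rows = np.nonzero(miss[c].to_numpy())[0]
            if len(rows):
                w = (Zhat[rows, j:j + len(lvs)] + np.sqrt(p)) * np.sqrt(p)
                w = np.clip(w, 0, None)
                norm = w.sum(axis=1, keepdims=True)
                w = np.where(norm > 0, w / norm, 1.0 / len(lvs))
                fuzzy[c] = w
                for r, weights in zip(rows, w):
                    work.at[work.index[r], c] = lvs[int(np.argmax(weights))]
            j += len(lvs)
        if prev is not None and delta < tol:
            break
        prev = delta
    else:
        warnings.warn("imputation did not converge; returning last iterate", stacklevel=2)
    return work


def group_hulls(coords: np.ndarray, labels, axes=(0, 1)) -> dict[str, np.ndarray]:
    """2-D convex hull vertices per group on a chosen axis pair."""
    from scipy.spatial import ConvexHull, QhullError

    pts2 = coords[:, list(axes)]
    labels = np.asarray(labels)
    hulls = {}
    for g in np.unique(labels):
        p = pts2[labels == g]
        if len(p) < 3:
            hulls[str(g)] = p
            continue
        try:
            h = ConvexHull(p)
            hulls[str(g)] = p[h.vertices]
        except QhullError:
            hulls[str(g)] = p
    return hulls


def plot_hulls(model: FAMDModel, labels, axes=(0, 1), path=None, cos2_cutoff: float = 0.56):
    """Biplot of rows with per-group convex hulls; display thresholds only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = axes
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.asarray(labels)
    for g in np.unique(labels):
        sel = labels == g
        ax.scatter(model.row_coords[sel, i], model.row_coords[sel, j], label=str(g), s=18)
    for g, hull in group_hulls(model.row_coords, labels, axes).items():
        if len(hull) >= 3:
            ax.fill(hull[:, 0], hull[:, 1], alpha=0.15)
    ax.set_xlabel(f"Axis {i + 1} ({model.pct_variance[i]:.1f}%)")
    ax.set_ylabel(f"Axis {j + 1} ({model.pct_variance[j]:.1f}%)")
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
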