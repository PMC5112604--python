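"""S-plots, biomarker selection, metabolite loading matrices and clustering.

An S-plot scatters, for every feature of every block, its covariance with the
consensus predictive score (effect magnitude) against its correlation with it
(reliability). Candidate biomarkers sit in the extreme quadrants: area 1
(cov > 0 and corr > 0, upregulation under the factor) and area 4 (both
negative, downregulation); areas 2/3 hold the non-selected remainder. Because
all blocks enter one model per factor, features from every analytical
protocol appear in a single combined S-plot.

Identified metabolites aggregate their characteristic ion features; their
mean covariances across all statistically significant factor models form a
metabolite x factor loading matrix that is clustered with Euclidean distances
and Ward linkage and rendered as a dendrogram + heat map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, dendrogram, leaves_list, linkage

__all__ = [
    "splot",
    "assign_area",
    "LoadingMatrix",
    "loading_matrix",
    "cluster_heatmap",
    "interpret_linked_factors",
]


def splot(model, blocks: dict[str, pd.DataFrame],
          features: dict[str, pd.DataFrame] | None = None,
          corr_threshold: float = 0.5,
          cov_quantile: float = 0.75) -> pd.DataFrame:
    """Combined S-plot table of a fitted consensus model.

    For feature j of block i (``blocks`` holds the scaled training matrices
    the model was fitted on): cov = t_p^T x_j / (n - 1) and corr =
    cov / (sd(t_p) sd(x_j)). Zero-variance features are excluded with a
    warning. Areas are assigned with the default thresholds; re-assign with
    :func:`assign_area`. ``features`` optionally supplies per-block m/z and
    retention-time annotations (``feature_id``, ``mz``, ``rt`` columns).
    """
    tp = np.asarray(model.scores_, dtype=float)
    n = len(tp)
    sd_t = tp.std(ddof=1)
    rows = []
    for name, X in blocks.items():
        X = pd.DataFrame(X)
        if X.shape[0] != n:
            raise ValueError(
                f"block {name!r} has {X.shape[0]} samples, model has {n}"
            )
        arr = X.to_numpy(dtype=float)
        arr_c = arr - arr.mean(axis=0)
        cov = (tp - tp.mean()) @ arr_c / (n - 1)
        sd_x = arr.std(axis=0, ddof=1)
        zero = sd_x == 0
        if zero.any():
            warnings.warn(
                f"block {name!r}: excluding {int(zero.sum())} zero-variance "
                "feature(s) from the S-plot", RuntimeWarning, stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = cov / (sd_t * sd_x)
        tab = pd.DataFrame({
            "block": name,
            "feature_id": X.columns.astype(str),
            "cov": cov,
            "corr": corr,
        }).loc[~zero]
        if features is not None and name in features:
            ann = features[name].set_index("feature_id")
            for col in ("mz", "rt", "latent_id"):
                if col in ann.columns:
                    tab[col] = ann[col].reindex(tab["feature_id"]).to_numpy()
        rows.append(tab)
    table = pd.concat(rows, ignore_index=True)
    return assign_area(table, corr_threshold, cov_quantile)


def assign_area(table: pd.DataFrame, corr_threshold: float = 0.5,
                cov_quantile: float = 0.75) -> pd.DataFrame:
    """Assign S-plot quadrant areas and return the table with ``area`` set.

    Area 1: corr >= corr_threshold and cov >= the ``cov_quantile`` quantile
    of the positive covariances. Area 4 mirrors both signs. Everything else
    is area 2 (cov >= 0) or 3 (cov < 0). Raising either threshold never adds
    a feature to areas 1/4. Select biomarkers as ``table[table.area.isin((1,
    4))]``.
    """
    if not (0 <= corr_threshold <= 1 and 0 <= cov_quantile <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    table = table.copy()
    cov, corr = table["cov"].to_numpy(), table["corr"].to_numpy()
    pos, neg = cov[cov > 0], -cov[cov < 0]
    cut_pos = np.quantile(pos, cov_quantile) if pos.size else np.inf
    cut_neg = np.quantile(neg, cov_quantile) if neg.size else np.inf
    area = np.where(cov >= 0, 2, 3)
    area[(corr >= corr_threshold) & (cov > 0) & (cov >= cut_pos)] = 1
    area[(corr <= -corr_threshold) & (cov < 0) & (-cov >= cut_neg)] = 4
    table["area"] = area
    return table


@dataclass
class LoadingMatrix:
    """Metabolite x significant-factor contribution matrix."""

    values: pd.DataFrame            # rows metabolites, columns factor models
    p_values: dict[str, float]      # per retained factor column
    dropped: list[str]              # metabolites with no surviving ion feature


def loading_matrix(splots: dict[str, pd.DataFrame],
                   p_values: dict[str, float],
                   metabolite_map: dict[str, list[str]],
                   p_cutoff: float = 0.05,
                   feature_key: str = "latent_id") -> LoadingMatrix:
    """Collect metabolite contributions across all significant factor models.

    ``splots`` maps factor/indicator name to its S-plot table; only factors
    with ``p_values[factor] < p_cutoff`` contribute columns. A cell is the
    mean covariance of the metabolite's ion features (matched on
    ``feature_key``) in that model's S-plot; its sign encodes up/down
    regulation. Metabolites with no surviving ion feature are dropped with a
    warning.
    """
    keep = [f for f in splots if p_values.get(f, 1.0) < p_cutoff]
    if not keep:
        raise ValueError("no factor model passes the significance cutoff")
    rows, dropped = {}, []
    for met, ions in metabolite_map.items():
        cells = {}
        for fac in keep:
            tab = splots[fac]
            key = tab[feature_key] if feature_key in tab else tab["feature_id"]
            sub = tab.loc[key.isin(ions), "cov"]
            cells[fac] = float(sub.mean()) if len(sub) else np.nan
        if all(np.isnan(v) for v in cells.values()):
            dropped.append(met)
            warnings.warn(
                f"metabolite {met!r}: no surviving ion feature in any "
                "significant model; row dropped", RuntimeWarning, stacklevel=2,
            )
            continue
        rows[met] = cells
    values = pd.DataFrame.from_dict(rows, orient="index")[keep]
    return LoadingMatrix(
        values=values,
        p_values={f: p_values[f] for f in keep},
        dropped=dropped,
    )


def cluster_heatmap(matrix: LoadingMatrix | pd.DataFrame,
                    out_png: str | None = None):
    """Ward/Euclidean clustering of metabolite rows, plus an optional figure.

    Rows are sorted by label before linkage so the leaf order is
    deterministic and seed-free. Returns ``(linkage_matrix, leaf_labels,
    cophenetic_distances)``; if ``out_png`` is given, a dendrogram + heat map
    with a diverging colormap centered at 0 is written there.
    """
    values = matrix.values if isinstance(matrix, LoadingMatrix) else matrix
    if values.isna().any().any():
        raise ValueError("loading matrix has missing cells; rows must be complete")
    if len(values) < 2:
        raise ValueError("need at least 2 rows to cluster")
    values = values.sort_index()
    Z = linkage(values.to_numpy(), method="ward", metric="euclidean")
    order = leaves_list(Z)
    leaf_labels = [values.index[i] for i in order]
    coph = cophenet(Z)
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax_d, ax_h) = plt.subplots(
            1, 2, figsize=(10, max(4, 0.25 * len(values))),
            gridspec_kw={"width_ratios": [1, 3]},
        )
        dendrogram(Z, orientation="left", labels=list(values.index), ax=ax_d,
                   color_threshold=0)
        data = values.iloc[order].to_numpy()
        vmax = np.nanmax(np.abs(data)) or 1.0
        im = ax_h.pcolormesh(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax_h.set_yticks(np.arange(len(order)) + 0.5)
        ax_h.set_yticklabels(leaf_labels, fontsize=6)
        ax_h.set_xticks(np.arange(values.shape[1]) + 0.5)
        ax_h.set_xticklabels(values.columns, rotation=90, fontsize=7)
        fig.colorbar(im, ax=ax_h, label="contribution (cov with t_p)")
        fig.tight_layout()
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return Z, leaf_labels, coph


def interpret_linked_factors(matrix: LoadingMatrix | pd.DataFrame,
                             factor_groups: dict[str, list[str]],
                             strong_threshold: float | None = None
                             ) -> pd.DataFrame:
    """Consistency check for one-vs-rest hormone indicator groups.

    Within a hormone family exactly one member is present per run, so the
    family's indicator columns sum to one: if every family member shows the
    same strong-signed contribution for a metabolite, the pattern violates
    that linear dependence (e.g. three auxins down implies the fourth up,
    relative to the others). Report only; nothing is mutated. ``strong_
    threshold`` defaults to half the median |cell| of the matrix.
    """
    values = matrix.values if isinstance(matrix, LoadingMatrix) else matrix
    if strong_threshold is None:
        strong_threshold = 0.5 * float(np.nanmedian(np.abs(values.to_numpy()))) \
            if values.size else 0.0
    records = []
    for group, members in factor_groups.items():
        cols = [m for m in members if m in values.columns]
        if len(cols) < 2:
            continue  # vacuously consistent
        sub = values[cols]
        strong = (sub.abs() >= strong_threshold) & sub.notna()
        same_pos = (sub.gt(0) & strong).all(axis=1)
        same_neg = (sub.lt(0) & strong).all(axis=1)
        for met in values.index:
            flagged = bool(same_pos[met] or same_neg[met])
            records.append({
                "metabolite": met, "group": group, "consistent": not flagged,
            })
    return pd.DataFrame.from_records(
        records, columns=["metabolite", "group", "consistent"]
    )
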