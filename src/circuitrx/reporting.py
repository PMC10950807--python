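"""Pipeline orchestration, result files, plots and drug-level summaries.

``run_pipeline`` executes the full validated procedure for a disease env
file: dataset assembly, optional imputation and hyperparameter tuning, the
resampling validation harness, a final fit, and the two result TSVs
(`shap_summary.tsv`, the per-circuit score table; and
`shap_selection_relevance.tsv`, the repurposing profile S') plus a JSON
metadata sidecar.

Stability estimates are banded following the effect sizes of the stability
literature: poor (s <= 0.4), mid (0.4 < s < 0.75), excellent (s >= 0.75).
The plotting helpers render the stability/R² summary and the per-circuit
scaled relevance heatmap; drug-level views rank drugs by the l1 norm of
their targets' signed relevances and aggregate them per pathway over the
stable circuits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .config import parse_disease_env
from .disease_map import build_disease_dataset
from .errors import CircuitrxError, ConfigurationError, MapLookupError
from .io import load_drug_table, load_gene_table, read_labeled_matrix, write_labeled_matrix
from .morf import MorfHyperparams, impute_knn, tune_successive_halving
from .selection import (
    DEFAULT_N_SPLITS,
    DEFAULT_QUANTILE_THRESHOLD,
    DEFAULT_R2_THRESHOLD,
    MAP_AVERAGE_LABEL,
    bootstrap_evaluate,
    final_fit,
)

SCORES_FILENAME = "shap_summary.tsv"
RELEVANCE_FILENAME = "shap_selection_relevance.tsv"
METADATA_FILENAME = "run_metadata.json"

BAND_POOR = "poor"
BAND_MID = "mid"
BAND_EXCELLENT = "excellent"
_BAND_COLORS = {BAND_POOR: "#d62728", BAND_MID: "#e6c229", BAND_EXCELLENT: "#2ca02c"}
STABILITY_PLOT_FILTER = 0.4  # circuits with stability CI lower bound below this are hidden


def stability_band(s: float) -> str:
    """Effect-size band of a stability estimate (total on the reals)."""
    if s <= 0.4:
        return BAND_POOR
    if s < 0.75:
        return BAND_MID
    return BAND_EXCELLENT


def run_pipeline(
    env_path: str | Path,
    n_cpus: int = 1,
    n_iters: int = 0,
    seed: int = 0,
    n_splits: int = DEFAULT_N_SPLITS,
    q_th: float = DEFAULT_QUANTILE_THRESHOLD,
    r2_th: float = DEFAULT_R2_THRESHOLD,
    output_dir: str | Path | None = None,
) -> Path:
    """Run the full validation procedure and a final fit for a disease env.

    Writes the score table, the repurposing profile S' and a metadata
    sidecar into *output_dir* (default ``<env dir>/results``); byte-identical
    outputs for identical inputs and seed.
    """
    env_path = Path(env_path)
    config = parse_disease_env(env_path)
    out = Path(output_dir) if output_dir is not None else env_path.resolve().parent / "results"
    out.mkdir(parents=True, exist_ok=True)

    X, Y, dmap = build_disease_dataset(config)
    if X.isna().any().any():
        X = impute_knn(X)

    if n_iters > 0:
        hp = tune_successive_halving(X, Y, n_iters=n_iters, seed=seed)
    else:
        hp = MorfHyperparams(random_seed=seed)
    hp = hp.resolve(X.shape[1])

    boot = bootstrap_evaluate(
        X, Y, n_splits=n_splits, hp=hp, q_th=q_th, r2_th=r2_th, seed=seed, n_cpus=n_cpus
    )
    r2_gate = boot.scores.drop(index=MAP_AVERAGE_LABEL)["r2_point"]
    sprime, _, _ = final_fit(
        X, Y, hp=hp, q_th=q_th, r2_th=r2_th, r2_gate=r2_gate, seed=seed + 1
    )

    boot.scores.to_csv(out / SCORES_FILENAME, sep="\t", lineterminator="\n")
    write_labeled_matrix(sprime, out / RELEVANCE_FILENAME)

    metadata = {
        "package_version": __version__,
        "seed": seed,
        "n_splits": n_splits,
        "n_iters": n_iters,
        "q_th": q_th,
        "r2_th": r2_th,
        "hyperparams": {
            "n_trees": hp.n_trees,
            "max_depth": hp.max_depth,
            "max_features_per_split": hp.max_features_per_split,
        },
        "disease_env": str(env_path.resolve()),
        "map_provenance": dmap.provenance,
        "n_samples": int(X.shape[0]),
        "n_kdt": int(X.shape[1]),
        "n_circuits": int(Y.shape[1]),
        "versions": config.versions,
        "resources": {
            "genes": str(config.genes) if config.genes else None,
            "genes_column": config.genes_column,
            "drugs": str(config.drugs) if config.drugs else None,
            "circuit_map": str(config.circuit_map) if config.circuit_map else None,
        },
    }
    (out / METADATA_FILENAME).write_text(
        json.dumps(metadata, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out


def _circuit_scores(scores: pd.DataFrame) -> pd.DataFrame:
    return scores.drop(index=MAP_AVERAGE_LABEL, errors="ignore")


def plot_stability_summary(scores: pd.DataFrame, out_prefix: str | Path):
    """Stability (x) versus R² (y, with CI bars) per circuit, on colored
    effect-size bands; writes ``<prefix>.png`` and ``<prefix>.pdf``."""
    circuits = _circuit_scores(scores)
    if circuits.empty:
        raise ConfigurationError("empty score table, nothing to plot")
    fig, ax = plt.subplots(figsize=(7, 5))
    xmin = min(-0.05, np.nanmin(circuits["stability_point"].to_numpy()) - 0.05)
    ax.axvspan(xmin, 0.4, color=_BAND_COLORS[BAND_POOR], alpha=0.15)
    ax.axvspan(0.4, 0.75, color=_BAND_COLORS[BAND_MID], alpha=0.15)
    ax.axvspan(0.75, 1.0, color=_BAND_COLORS[BAND_EXCELLENT], alpha=0.15)
    yerr = np.vstack(
        [
            (circuits["r2_point"] - circuits["r2_lo"]).clip(lower=0),
            (circuits["r2_hi"] - circuits["r2_point"]).clip(lower=0),
        ]
    )
    xerr = np.vstack(
        [
            (circuits["stability_point"] - circuits["stability_lo"]).clip(lower=0),
            (circuits["stability_hi"] - circuits["stability_point"]).clip(lower=0),
        ]
    )
    ax.errorbar(
        circuits["stability_point"],
        circuits["r2_point"],
        xerr=xerr,
        yerr=yerr,
        fmt="o",
        color="black",
        ecolor="gray",
        capsize=2,
    )
    for name, row in circuits.iterrows():
        ax.annotate(str(name), (row["stability_point"], row["r2_point"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("Nogueira stability")
    ax.set_ylabel("R² (validation)")
    ax.set_xlim(xmin, 1.02)
    fig.tight_layout()
    paths = _save_both(fig, out_prefix)
    return fig, paths


def relevance_display_frame(
    sprime: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """The circuits-x-KDTs frame the heatmap displays.

    Circuits whose stability CI lower bound is poor (< 0.4) are excluded,
    all-zero circuits and KDT columns are dropped, and each remaining
    circuit row is scaled to (-1, 1) by dividing by its max |S'|.
    """
    circuits = _circuit_scores(scores)
    display = sprime.T  # rows = circuits, columns = KDTs
    keep = [
        c
        for c in display.index
        if c in circuits.index and circuits.loc[c, "stability_lo"] >= STABILITY_PLOT_FILTER
    ]
    dropped_stability = [c for c in display.index if c not in keep]
    display = display.loc[keep]
    display = display.loc[(display != 0).any(axis=1)]
    if display.empty:
        raise ConfigurationError(
            "nothing to display: all circuits removed by the stability filter "
            f"(dropped: {dropped_stability[:5]}) or have empty selections"
        )
    display = display.loc[:, (display != 0).any(axis=0)]
    scale = display.abs().max(axis=1)
    return display.div(scale, axis=0)


def _action_colors(kdts: list[str], drug_table: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Most frequent drug action per KDT (mode, ties lexicographic)."""
    actions = {}
    grouped = drug_table.assign(target=drug_table["target_entrez"].astype(str)).groupby("target")
    for target, grp in grouped:
        counts = grp["action"].value_counts()
        top = counts[counts == counts.max()].index.sort_values()[0]
        actions[target] = top
    per_kdt = pd.Series({k: actions.get(k, "none") for k in kdts}, name="drug action")
    palette = {"inhibitor": "#1f77b4", "activator": "#ff7f0e", "other": "#7f7f7f", "none": "#ffffff"}
    extra = [a for a in sorted(set(per_kdt)) if a not in palette]
    cmap = plt.get_cmap("tab10")
    for i, a in enumerate(extra):
        palette[a] = matplotlib.colors.to_hex(cmap(i + 3))
    return per_kdt, palette


def plot_relevance_clustermap(
    sprime: pd.DataFrame,
    scores: pd.DataFrame,
    out_prefix: str | Path,
    drug_table: pd.DataFrame | None = None,
    gene: str | None = None,
    gene_table: pd.DataFrame | None = None,
):
    """Clustered heatmap of the per-circuit scaled repurposing profile.

    Columns (KDTs) carry a color bar with the most frequent drug action
    among the drugs targeting each KDT.  With *gene* set, only that KDT's
    column profile is rendered (accepts an Entrez id, or a symbol when a
    gene table is given).
    """
    import seaborn as sns

    display = relevance_display_frame(sprime, scores)

    if gene is not None:
        target = _resolve_gene(gene, list(display.columns), gene_table)
        fig, ax = plt.subplots(figsize=(5, max(2, 0.4 * display.shape[0])))
        display[target].plot.barh(ax=ax, color="#1f77b4")
        ax.set_xlabel(f"scaled signed relevance of {gene}")
        ax.set_xlim(-1.05, 1.05)
        fig.tight_layout()
        paths = _save_both(fig, out_prefix)
        return fig, paths

    col_colors = None
    if drug_table is not None:
        per_kdt, palette = _action_colors(list(display.columns), drug_table)
        col_colors = per_kdt.map(palette)

    if display.shape[0] < 2 or display.shape[1] < 2:
        fig, ax = plt.subplots(figsize=(8, 4))
        sns.heatmap(display, cmap="vlag", center=0, vmin=-1, vmax=1, ax=ax)
        fig.tight_layout()
        paths = _save_both(fig, out_prefix)
        return fig, paths

    grid = sns.clustermap(
        display,
        cmap="vlag",
        center=0,
        vmin=-1,
        vmax=1,
        metric="correlation",
        method="average",
        col_colors=col_colors,
        figsize=(max(6, 0.3 * display.shape[1]), max(4, 0.4 * display.shape[0])),
    )
    paths = _save_both(grid.figure, out_prefix)
    return grid.figure, paths


def _resolve_gene(gene: str, kdts: list[str], gene_table: pd.DataFrame | None) -> str:
    if gene in kdts:
        return gene
    if gene_table is not None:
        match = gene_table[gene_table["symbol_id"].astype(str) == str(gene)]
        if not match.empty:
            entrez = str(int(match["entrez_id"].iloc[0]))
            if entrez in kdts:
                return entrez
    raise MapLookupError(f"gene {gene!r} is not among the displayed KDTs")


def _save_both(fig, out_prefix: str | Path) -> list[Path]:
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for ext in ("png", "pdf"):
        p = out_prefix.with_suffix(f".{ext}")
        fig.savefig(p, dpi=150)
        paths.append(p)
    return paths


@dataclass
class DrugProfile:
    """Drug-level reduction of the repurposing profile."""

    ranking: pd.DataFrame  # top_n drugs: drug_name, l1_norm, descending
    relevance: pd.DataFrame  # drug x circuit summed target relevance (ranked drugs)
    by_pathway: pd.DataFrame  # drug x pathway aggregation over stable circuits


def rank_drugs(
    sprime: pd.DataFrame,
    drug_table: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    circuit_pathways: pd.Series | dict | None = None,
    top_n: int = 30,
) -> DrugProfile:
    """Rank drugs by the l1 norm of their targets' signed relevances.

    A drug's relevance over circuits is the element-wise sum of its
    targets' S' rows; its l1 norm sums the absolute values over circuits.
    Ties in the ranking break lexicographically by drug id.  The pathway
    aggregation sums each drug's relevance over the *stable* circuits
    (stability CI lower bound >= 0.4 when a score table is given) within
    each pathway.
    """
    kdts = set(sprime.index)
    table = drug_table.assign(target=drug_table["target_entrez"].astype(str))
    table = table[table["target"].isin(kdts)]
    if table.empty:
        raise MapLookupError("no drug target intersects the repurposing profile KDTs")

    rows = {}
    names = {}
    for (drug_id, drug_name), grp in table.groupby(["drug_id", "drug_name"]):
        rows[drug_id] = sprime.loc[grp["target"].unique()].sum(axis=0)
        names[drug_id] = drug_name
    relevance = pd.DataFrame(rows).T  # drug x circuit
    l1 = relevance.abs().sum(axis=1)
    ranking = pd.DataFrame({"drug_name": pd.Series(names), "l1_norm": l1})
    # ties break lexicographically by drug id (the index)
    ranking = ranking.sort_index().sort_values("l1_norm", ascending=False, kind="mergesort")
    ranking = ranking.iloc[:top_n]
    relevance = relevance.loc[ranking.index]

    if scores is not None:
        circ = _circuit_scores(scores)
        stable = [
            c
            for c in relevance.columns
            if c in circ.index and circ.loc[c, "stability_lo"] >= STABILITY_PLOT_FILTER
        ]
    else:
        stable = list(relevance.columns)
    if circuit_pathways is None:
        circuit_pathways = {
            c: (str(c).split(":")[0].strip() if ":" in str(c) else str(c))
            for c in relevance.columns
        }
    pathways = pd.Series(circuit_pathways)
    stable_rel = relevance[stable]
    by_pathway = stable_rel.T.groupby(pathways.reindex(stable)).sum().T
    ranking.index.name = "drug_id"
    return DrugProfile(ranking=ranking, relevance=relevance, by_pathway=by_pathway)


def load_results(results_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read back a results directory: (scores, S', metadata)."""
    results_dir = Path(results_dir)
    scores = pd.read_csv(results_dir / SCORES_FILENAME, sep="\t", index_col=0)
    sprime = read_labeled_matrix(results_dir / RELEVANCE_FILENAME)
    meta_path = results_dir / METADATA_FILENAME
    metadata = json.loads(meta_path.read_text(encoding="utf-8")) if meta_path.exists() else {}
    return scores, sprime, metadata


def plot_results(results_dir: str | Path, gene: str | None = None) -> list[Path]:
    """Render the stability summary and relevance heatmap for a results dir."""
    results_dir = Path(results_dir)
    scores, sprime, metadata = load_results(results_dir)
    resources = metadata.get("resources", {})
    drug_table = None
    gene_table = None
    try:
        if resources.get("drugs"):
            drug_table = load_drug_table(resources["drugs"])
        if resources.get("genes"):
            gene_table = load_gene_table(
                resources["genes"], resources.get("genes_column", "drugbank_approved_targets")
            )
    except (OSError, CircuitrxError) as exc:
        warnings.warn(f"resource table unavailable for plotting annotations: {exc}", stacklevel=2)

    written: list[Path] = []
    fig, paths = plot_stability_summary(scores, results_dir / "stability_summary")
    plt.close(fig)
    written += paths
    prefix = "relevance_heatmap" if gene is None else f"relevance_{gene}"
    fig, paths = plot_relevance_clustermap(
        sprime, scores, results_dir / prefix, drug_table=drug_table, gene=gene,
        gene_table=gene_table,
    )
    plt.close(fig)
    written += paths
    return written
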