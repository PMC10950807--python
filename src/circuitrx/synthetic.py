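"""Synthetic datasets with planted KDT→circuit dependencies.

The generator emulates the inputs the pipeline consumes — a normalized
expression matrix over known drug targets and a circuit-activity matrix —
with a known ground truth: each circuit's activity is driven by a small
set of driver KDTs through a linear or threshold link plus Gaussian noise.
Expression is standard normal per gene (the method consumes normalized
expression, so count-level realism is unnecessary); driver weights have
magnitude in [0.5, 1.5] with random signs, and drivers may overlap across
circuits (pleiotropic targets exist in real maps).

A companion generator writes a miniature, internally consistent resource
set (gene table, circuit map, drug table, gene-disease table, matrices and
a disease env file) so the full command-line pipeline runs end-to-end on
files of the exact formats the tool consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import write_labeled_matrix

DEFAULT_NOISE_SD = 0.3


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic dataset: per-circuit driver sets."""

    drivers: dict[str, list[str]]  # circuit id -> driver KDT column ids
    weights: dict[str, np.ndarray]  # circuit id -> driver weights
    link: str  # "linear" | "threshold"
    noise_sd: float


def generate_synthetic_dataset(
    n_samples: int = 500,
    n_kdt: int = 50,
    n_circuits: int = 5,
    drivers_per_circuit: int = 3,
    noise_sd: float = DEFAULT_NOISE_SD,
    link: str = "linear",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Expression X, activity Y and the planted truth, deterministic by seed.

    Y_k = sum_{i in drivers_k} w_i g(X_i) + N(0, noise_sd^2), with g the
    identity ("linear") or an indicator g(x) = 1[x > 0] ("threshold").
    """
    if drivers_per_circuit > n_kdt:
        raise ConfigurationError("drivers_per_circuit cannot exceed n_kdt")
    if drivers_per_circuit < 1 or n_samples < 2 or n_kdt < 1 or n_circuits < 1:
        raise ConfigurationError("invalid synthetic dataset sizes")
    if link not in ("linear", "threshold"):
        raise ConfigurationError(f"unknown link {link!r}")
    rng = np.random.default_rng(seed)
    genes = [str(1000 + i) for i in range(n_kdt)]
    circuits = [f"C{k}" for k in range(n_circuits)]
    samples = [f"sample{i}" for i in range(n_samples)]

    X = rng.normal(size=(n_samples, n_kdt))
    Y = np.empty((n_samples, n_circuits))
    drivers: dict[str, list[str]] = {}
    weights: dict[str, np.ndarray] = {}
    for k, circuit in enumerate(circuits):
        idx = rng.choice(n_kdt, size=drivers_per_circuit, replace=False)
        w = rng.uniform(0.5, 1.5, size=drivers_per_circuit) * rng.choice([-1.0, 1.0], size=drivers_per_circuit)
        g = X[:, idx] if link == "linear" else (X[:, idx] > 0).astype(float)
        Y[:, k] = g @ w + rng.normal(scale=noise_sd, size=n_samples)
        drivers[circuit] = [genes[i] for i in idx]
        weights[circuit] = w
    Xdf = pd.DataFrame(X, index=samples, columns=genes)
    Ydf = pd.DataFrame(Y, index=samples, columns=circuits)
    truth = PlantedTruth(drivers=drivers, weights=weights, link=link, noise_sd=noise_sd)
    return Xdf, Ydf, truth


def inject_missingness(X: pd.DataFrame, fraction: float, seed: int = 0) -> pd.DataFrame:
    """Set exactly floor(fraction * cells) cells to NaN, never emptying a
    column; deterministic by seed."""
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError(f"missing fraction must lie in [0, 1), got {fraction}")
    n_missing = int(fraction * X.size)
    if n_missing == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    n_rows, n_cols = X.shape
    for _ in range(100):
        flat = rng.choice(X.size, size=n_missing, replace=False)
        rows, cols = np.unravel_index(flat, X.shape)
        per_col = np.bincount(cols, minlength=n_cols)
        if (per_col < n_rows).all():
            values = X.to_numpy(dtype=float, copy=True)
            values[rows, cols] = np.nan
            return pd.DataFrame(values, index=X.index, columns=X.columns)
    raise ConfigurationError("could not place missing cells without emptying a column")


_ACTIONS = ("inhibitor", "activator", "other")


def generate_fixture_resources(
    out_dir: str | Path,
    n_kdt: int = 20,
    n_circuits: int = 4,
    n_drugs: int = 8,
    n_samples: int = 120,
    drivers_per_circuit: int = 3,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> Path:
    """Write a self-consistent miniature resource set and return the env path.

    The circuit map's gene sets contain the planted drivers of each circuit
    (plus decoys), so seed-gene construction and the planted truth agree.
    Files: gene_exp.tsv, pathvals.tsv, genes.tsv, circuit_map.tsv,
    circuits.tsv, drugs.tsv, gene_disease.tsv, disease.env, truth.tsv.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    X, Y, truth = generate_synthetic_dataset(
        n_samples=n_samples,
        n_kdt=n_kdt,
        n_circuits=n_circuits,
        drivers_per_circuit=drivers_per_circuit,
        noise_sd=noise_sd,
        seed=seed,
    )
    kdt_ids = [int(g) for g in X.columns]
    extra_ids = [max(kdt_ids) + 1 + i for i in range(max(2, n_kdt // 4))]  # non-KDT genes

    pathways = [f"Pathway {chr(ord('A') + k % 26)}" for k in range(n_circuits)]
    symbols = {g: f"G{g}" for g in kdt_ids + extra_ids}

    gene_table = pd.DataFrame(
        {
            "entrez_id": kdt_ids + extra_ids,
            "symbol_id": [symbols[g] for g in kdt_ids + extra_ids],
            "drugbank_approved_targets": [True] * len(kdt_ids) + [False] * len(extra_ids),
        }
    )
    gene_table.to_csv(out_dir / "genes.tsv", sep="\t", index=False)

    circuit_rows = []
    for k, circuit in enumerate(Y.columns):
        driver_genes = [int(g) for g in truth.drivers[circuit]]
        effector = driver_genes[0]
        decoys = rng.choice(extra_ids, size=min(2, len(extra_ids)), replace=False).tolist()
        gene_list = driver_genes + decoys
        circuit_rows.append(
            {
                "circuit_id": circuit,
                "circuit_name": f"{pathways[k]}: {symbols[effector]}",
                "pathway_name": pathways[k],
                "gene_list": ",".join(str(g) for g in gene_list),
                "is_physiological": bool(k % 4 != 3),  # one in four flagged non-physio
            }
        )
    circuit_map = pd.DataFrame(circuit_rows)
    circuit_map.to_csv(out_dir / "circuit_map.tsv", sep="\t", index=False)

    circuits_tsv = pd.DataFrame(
        {"in_disease": [1] * n_circuits}, index=circuit_map["circuit_id"]
    )
    circuits_tsv.index.name = "circuit"
    circuits_tsv.to_csv(out_dir / "circuits.tsv", sep="\t")

    drug_rows = []
    for d in range(n_drugs):
        n_targets = int(rng.integers(1, 3))
        targets = rng.choice(kdt_ids, size=n_targets, replace=False)
        # cycle actions so every category occurs
        action = _ACTIONS[d % len(_ACTIONS)]
        for t in targets:
            drug_rows.append(
                {
                    "drug_id": f"DB{10000 + d}",
                    "drug_name": f"drug{d}",
                    "target_entrez": int(t),
                    "action": action,
                }
            )
    pd.DataFrame(drug_rows).drop_duplicates(subset=["drug_id", "target_entrez"]).to_csv(
        out_dir / "drugs.tsv", sep="\t", index=False
    )

    seed_pool = sorted({int(g) for ds in truth.drivers.values() for g in ds})
    gene_disease = pd.DataFrame(
        {
            "disease_id": ["C0015625"] * len(seed_pool),
            "entrez_id": seed_pool,
            "score": np.round(rng.uniform(0.3, 1.0, size=len(seed_pool)), 3),
        }
    )
    gene_disease.to_csv(out_dir / "gene_disease.tsv", sep="\t", index=False)

    write_labeled_matrix(X, out_dir / "gene_exp.tsv")
    write_labeled_matrix(Y, out_dir / "pathvals.tsv")

    truth_rows = [
        {"circuit_id": c, "drivers": ",".join(truth.drivers[c])} for c in Y.columns
    ]
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)

    env = "\n".join(
        [
            "# synthetic disease definition (generated fixture)",
            "circuits=circuits.tsv",
            "circuits_column=in_disease",
            "use_physio=false",
            "activity_normalizer=false",
            "gene_exp=gene_exp.tsv",
            "pathvals=pathvals.tsv",
            "genes=genes.tsv",
            "genes_column=drugbank_approved_targets",
            "drugs=drugs.tsv",
            "gene_disease=gene_disease.tsv",
            "circuit_map=circuit_map.tsv",
        ]
    )
    (out_dir / "disease.env").write_text(env + "\n", encoding="utf-8")
    return out_dir / "disease.env"
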