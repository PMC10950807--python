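"""Disease-map assembly.

A disease map is the ordered list of signaling circuits (effector
subpathways, named ``"Pathway Name: effector gene"``) taken to represent
the disease mechanism.  It can be built three ways, in priority order when
several are configured: an explicit circuit list, a disease identifier
(UMLS CUI) resolved to seed genes through a gene-disease association table,
or a direct seed-gene list.  Seed genes select every circuit containing at
least one of them.  Optionally the map is trimmed to the physiological
circuit list.  Finally the expression and activity matrices are restricted
to the known drug targets and the map circuits, row-aligned on the shared
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import DiseaseConfig
from .errors import (
    AlignmentError,
    ConfigurationError,
    EmptyMapError,
    FormatError,
    MapLookupError,
)
from .io import kdt_genes, load_gene_table, read_labeled_matrix


@dataclass
class DiseaseMap:
    """Ordered, unique circuit identifiers plus how they were derived."""

    circuits: list[str]
    provenance: str  # "explicit" | "disease_id" | "seed_genes"

    def __post_init__(self) -> None:
        if len(set(self.circuits)) != len(self.circuits):
            raise FormatError("disease map contains duplicate circuits")
        if not self.circuits:
            raise EmptyMapError("disease map is empty")


def load_circuit_map(path: str | Path) -> pd.DataFrame:
    """Load the circuit→gene resource table.

    Columns: ``circuit_id``, ``circuit_name`` ("Pathway: effector"),
    ``pathway_name``, ``gene_list`` (comma-separated Entrez) and
    ``is_physiological``.  ``gene_set`` is added as a frozenset of ints.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("circuit_id", "circuit_name", "pathway_name", "gene_list", "is_physiological"):
        if col not in df.columns:
            raise FormatError(f"{path}: circuit map missing required column {col!r}")
    if df["circuit_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate circuit_id values")
    df["gene_set"] = df["gene_list"].map(
        lambda s: frozenset(int(g) for g in str(s).split(",") if str(g).strip())
    )
    if (df["gene_set"].map(len) == 0).any():
        raise FormatError(f"{path}: circuit with empty gene_list")
    df["is_physiological"] = df["is_physiological"].astype(bool)
    return df


def circuits_from_seed_genes(seeds: set[int], circuit_map: pd.DataFrame) -> DiseaseMap:
    """Circuits containing at least one seed gene, in resource-table order."""
    seeds = set(int(s) for s in seeds)
    if not seeds:
        raise ConfigurationError("seed gene set is empty")
    covered: set[int] = set()
    hits = []
    for _, row in circuit_map.iterrows():
        inter = row["gene_set"] & seeds
        if inter:
            hits.append(row["circuit_id"])
            covered |= inter
    missing = seeds - covered
    if missing:
        warnings.warn(
            f"seed genes absent from every circuit: {sorted(missing)}", stacklevel=2
        )
    if not hits:
        raise EmptyMapError(f"no circuit contains any of the seed genes {sorted(seeds)}")
    return DiseaseMap(circuits=hits, provenance="seed_genes")


def seed_genes_from_disease_id(
    disease_id: str,
    associations: pd.DataFrame,
    score_threshold: float = 0.0,
) -> set[int]:
    """Genes associated with a UMLS CUI, optionally score-filtered.

    The association table has columns ``disease_id``, ``entrez_id`` and
    ``score`` (a curated gene-disease association score in [0, 1]).  The
    default threshold 0.0 keeps every curated association.
    """
    for col in ("disease_id", "entrez_id", "score"):
        if col not in associations.columns:
            raise FormatError(f"gene-disease table missing required column {col!r}")
    rows = associations[associations["disease_id"] == disease_id]
    if rows.empty:
        raise MapLookupError(f"unknown disease identifier {disease_id!r}")
    rows = rows[rows["score"] >= score_threshold]
    if rows.empty:
        raise MapLookupError(
            f"no gene association for {disease_id!r} at score >= {score_threshold}"
        )
    return set(rows["entrez_id"].astype(int))


def filter_physiological(
    dmap: DiseaseMap, circuit_map: pd.DataFrame, use_physio: bool
) -> DiseaseMap:
    """Optionally keep only circuits on the physiological list (idempotent)."""
    if not use_physio:
        return dmap
    physio = set(circuit_map.loc[circuit_map["is_physiological"], "circuit_id"])
    kept = [c for c in dmap.circuits if c in physio]
    if not kept:
        raise EmptyMapError("physiological filter removed every circuit")
    return DiseaseMap(circuits=kept, provenance=dmap.provenance)


def resolve_circuits(
    spec: list[str] | str | Path,
    circuit_map: pd.DataFrame,
    circuits_column: str = "in_disease",
) -> DiseaseMap:
    """Resolve an explicit circuit list (names, ids, or indicator TSV).

    A TSV variant is indexed by circuit name/id with a binary column named
    *circuits_column*; rows flagged 1 are kept in file order.  Circuit
    names and identifiers are both accepted and resolved to identifiers.
    """
    if isinstance(spec, (str, Path)):
        table = pd.read_csv(spec, sep="\t", index_col=0)
        if circuits_column not in table.columns:
            raise FormatError(f"{spec}: missing circuit indicator column {circuits_column!r}")
        flags = table[circuits_column]
        bad = flags[~flags.isin([0, 1, True, False])]
        if not bad.empty:
            raise FormatError(
                f"{spec}: non-binary values in {circuits_column!r}: {bad.head(3).tolist()}"
            )
        names = [str(ix) for ix, flag in flags.items() if bool(flag)]
    else:
        names = [str(s) for s in spec]

    by_id = dict(zip(circuit_map["circuit_name"], circuit_map["circuit_id"]))
    ids = set(circuit_map["circuit_id"])
    resolved, unknown = [], []
    for name in names:
        if name in ids:
            resolved.append(name)
        elif name in by_id:
            resolved.append(by_id[name])
        else:
            unknown.append(name)
    if unknown:
        raise MapLookupError(f"unknown circuit(s): {unknown}")
    if not resolved:
        raise EmptyMapError("explicit circuit selection is empty")
    return DiseaseMap(circuits=resolved, provenance="explicit")


def build_disease_map(
    config: DiseaseConfig,
    circuit_map: pd.DataFrame,
    associations: pd.DataFrame | None = None,
    score_threshold: float = 0.0,
) -> DiseaseMap:
    """Build the disease map from a config, with route priority
    circuits > disease_id > seed_genes (warning when several are set)."""
    sources = [
        name
        for name, val in (
            ("circuits", config.circuits),
            ("disease_id", config.disease_id),
            ("seed_genes", config.seed_genes),
        )
        if val is not None
    ]
    if len(sources) > 1:
        warnings.warn(
            f"multiple map sources set ({sources}); using {sources[0]!r}", stacklevel=2
        )
    if config.circuits is not None:
        dmap = resolve_circuits(config.circuits, circuit_map, config.circuits_column)
    elif config.disease_id is not None:
        if associations is None:
            raise ConfigurationError(
                "disease_id route requires a gene-disease association table "
                "(gene_disease env key)"
            )
        seeds = seed_genes_from_disease_id(config.disease_id, associations, score_threshold)
        dmap = circuits_from_seed_genes(seeds, circuit_map)
        dmap = DiseaseMap(circuits=dmap.circuits, provenance="disease_id")
    else:
        dmap = circuits_from_seed_genes(set(config.seed_genes), circuit_map)
    return filter_physiological(dmap, circuit_map, config.use_physio)


def build_disease_dataset(
    config: DiseaseConfig,
    score_threshold: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, DiseaseMap]:
    """Assemble the model inputs: X (samples x KDT genes) and Y (samples x
    map circuits), row-aligned on the shared samples in X's file order.

    Requires ``gene_exp``, ``pathvals``, ``genes`` and ``circuit_map``
    paths in the config (plus ``gene_disease`` for the disease_id route).
    """
    for key in ("gene_exp", "pathvals", "genes", "circuit_map"):
        if getattr(config, key) is None:
            raise ConfigurationError(f"missing required data path {key!r} in disease env")

    expression = read_labeled_matrix(config.gene_exp)
    activity = read_labeled_matrix(config.pathvals)
    gene_table = load_gene_table(config.genes, config.genes_column)
    circuit_map = load_circuit_map(config.circuit_map)
    associations = (
        pd.read_csv(config.gene_disease, sep="\t") if config.gene_disease is not None else None
    )

    dmap = build_disease_map(config, circuit_map, associations, score_threshold)

    kdts = [str(g) for g in kdt_genes(gene_table, config.genes_column)]
    x_cols = [c for c in expression.columns if c in set(kdts)]
    y_cols = [c for c in dmap.circuits if c in set(activity.columns)]
    missing_circuits = [c for c in dmap.circuits if c not in set(activity.columns)]
    if missing_circuits:
        warnings.warn(
            f"{len(missing_circuits)} map circuit(s) absent from the activity matrix",
            stacklevel=2,
        )
    shared = [s for s in expression.index if s in set(activity.index)]
    if not shared:
        raise AlignmentError("expression and activity matrices share no samples")
    if len(x_cols) < 2:
        raise ConfigurationError(f"fewer than 2 KDT genes found in expression data ({x_cols})")
    if len(y_cols) < 2:
        raise ConfigurationError(f"fewer than 2 map circuits found in activity data ({y_cols})")

    X = expression.loc[shared, x_cols]
    Y = activity.loc[shared, y_cols]
    if config.activity_normalizer:
        span = Y.max() - Y.min()
        span = span.replace(0.0, 1.0)
        Y = (Y - Y.min()) / span
    return X, Y, DiseaseMap(circuits=y_cols, provenance=dmap.provenance)
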