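"""Disease definition files.

A disease is described by a plain-text environment file, one ``KEY=value``
per line.  Three complementary variables define the disease map: an explicit
circuit list (``circuits``), a disease identifier (``disease_id``, a UMLS
CUI such as ``C0015625``) whose associated genes become seed genes, or a
direct list of Entrez ``seed_genes``.  The remaining variables point at the
data matrices and resource tables and set binary switches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError

#: keys whose value is a filesystem path, resolved against the env file's dir
_PATH_KEYS = ("gene_exp", "pathvals", "genes", "drugs", "gene_disease", "circuit_map")
_BOOL_KEYS = ("use_physio", "activity_normalizer")
_VERSION_KEYS = (
    "GTEX_VERSION",
    "MYGENE_VERSION",
    "DRUGBANK_VERSION",
    "HIPATHIA_VERSION",
    "EDGER_VERSION",
)


@dataclass
class DiseaseConfig:
    """Parsed disease definition.

    ``circuits`` holds either a list of circuit names/identifiers or a path
    to a TSV with a binary indicator column (``circuits_column``).
    """

    seed_genes: list[int] | None = None
    disease_id: str | None = None
    circuits: list[str] | Path | None = None
    circuits_column: str = "in_disease"
    use_physio: bool = False
    activity_normalizer: bool = False
    gene_exp: Path | None = None
    pathvals: Path | None = None
    genes: Path | None = None
    genes_column: str = "drugbank_approved_targets"
    drugs: Path | None = None
    gene_disease: Path | None = None
    circuit_map: Path | None = None
    versions: dict[str, str] = field(default_factory=dict)
    extra: dict[str, str] = field(default_factory=dict)
    source_dir: Path | None = None

    def validate(self) -> None:
        if self.seed_genes is None and self.disease_id is None and self.circuits is None:
            raise ConfigurationError(
                "no disease-map source: set at least one of "
                "seed_genes, disease_id or circuits"
            )


def _strip_quotes(value: str) -> str:
    value = value.strip()
    if len(value) >= 2 and value[0] == value[-1] and value[0] in "\"'":
        value = value[1:-1]
    return value


def _parse_bool(key: str, value: str) -> bool:
    low = value.strip().lower()
    if low == "true":
        return True
    if low == "false":
        return False
    raise ConfigurationError(f"{key}: expected 'true' or 'false', got {value!r}")


def parse_disease_env(path: str | Path) -> DiseaseConfig:
    """Parse a disease definition env file into a :class:`DiseaseConfig`.

    Lines are ``KEY=value``; ``#`` starts a comment; quotes around values are
    stripped; comma-separated values of ``seed_genes`` and ``circuits`` parse
    as lists.  Relative paths resolve against the env file's directory.
    Unknown keys are preserved in ``extra`` and flagged with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"disease env file not found: {path}")
    base = path.resolve().parent

    cfg = DiseaseConfig(source_dir=base)
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path.name}:{lineno}: expected KEY=value, got {raw!r}")
        key, value = line.split("=", 1)
        key = key.strip()
        value = _strip_quotes(value)
        if key == "seed_genes":
            try:
                cfg.seed_genes = [int(v) for v in value.split(",") if v.strip()]
            except ValueError as exc:
                raise ConfigurationError(f"seed_genes: non-integer Entrez id in {value!r}") from exc
        elif key == "disease_id":
            cfg.disease_id = value
        elif key == "circuits":
            candidate = (base / value).expanduser()
            if value.endswith((".tsv", ".tsv.gz", ".feather")) or candidate.is_file():
                cfg.circuits = candidate
            else:
                cfg.circuits = [v.strip() for v in value.split(",") if v.strip()]
        elif key == "circuits_column":
            cfg.circuits_column = value
        elif key == "genes_column":
            cfg.genes_column = value
        elif key in _BOOL_KEYS:
            setattr(cfg, key, _parse_bool(key, value))
        elif key in _PATH_KEYS:
            setattr(cfg, key, (base / value).expanduser())
        elif key in _VERSION_KEYS:
            cfg.versions[key] = value
        else:
            warnings.warn(f"unknown disease-env key {key!r} (preserved)", stacklevel=2)
            cfg.extra[key] = value

    cfg.validate()
    return cfg


def serialize_disease_env(cfg: DiseaseConfig) -> str:
    """Render a config back to env-file text (inverse of the parser)."""
    lines: list[str] = []
    if cfg.seed_genes is not None:
        lines.append("seed_genes=" + ",".join(str(g) for g in cfg.seed_genes))
    if cfg.disease_id is not None:
        lines.append(f"disease_id={cfg.disease_id}")
    if cfg.circuits is not None:
        if isinstance(cfg.circuits, Path):
            lines.append(f"circuits={cfg.circuits}")
        else:
            lines.append("circuits=" + ",".join(cfg.circuits))
    lines.append(f"circuits_column={cfg.circuits_column}")
    lines.append(f"genes_column={cfg.genes_column}")
    lines.append(f"use_physio={'true' if cfg.use_physio else 'false'}")
    lines.append(f"activity_normalizer={'true' if cfg.activity_normalizer else 'false'}")
    for key in _PATH_KEYS:
        val = getattr(cfg, key)
        if val is not None:
            lines.append(f"{key}={val}")
    for key, val in cfg.versions.items():
        lines.append(f"{key}={val}")
    for key, val in cfg.extra.items():
        lines.append(f"{key}={val}")
    return "\n".join(lines) + "\n"
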