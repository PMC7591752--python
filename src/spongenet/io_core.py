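"""Domain containers, on-disk formats, configuration and logging.

Expression matrices are genes x samples TSV (first column gene id, header
row of sample ids); values are assumed to be already normalised (e.g.
log-scale microarray or log-CPM) — nothing here re-normalises.  Gene and
sample identifiers are opaque strings: no miRBase/Ensembl version lifting
is attempted.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("spongenet")

GENE_CLASSES = ("miRNA", "lncRNA", "mRNA")
TARGET_CLASSES = ("lncRNA", "mRNA")
GROUPS = ("case", "control")


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    """Structured logging to stderr; --verbose/--quiet map onto levels."""
    level = logging.DEBUG if verbose else (logging.ERROR if quiet else logging.INFO)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


class SpongenetError(ValueError):
    """Hard error raised on malformed inputs or violated contracts."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued matrix for one gene class.

    ``data`` is a pandas DataFrame indexed by gene id with sample ids as
    columns; ``group_labels`` maps every sample id to ``case`` or
    ``control``.
    """

    data: pd.DataFrame
    gene_class: str
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise SpongenetError(f"unknown gene class {self.gene_class!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SpongenetError(f"duplicated gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise SpongenetError(f"duplicated sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            # locate the first offending cell for the error message
            for gid, row in self.data.iterrows():
                for sid, cell in row.items():
                    try:
                        float(cell)
                    except (TypeError, ValueError):
                        raise SpongenetError(
                            f"non-numeric value {cell!r} at gene {gid!r}, sample {sid!r}"
                        ) from None
            raise SpongenetError("non-numeric expression matrix")
        if not np.isfinite(values.astype(float)).all():
            bad = np.argwhere(~np.isfinite(values.astype(float)))[0]
            raise SpongenetError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        missing = [s for s in self.data.columns if s not in self.group_labels]
        if missing:
            raise SpongenetError(f"samples missing from label file: {missing}")
        bad_groups = {g for g in self.group_labels.values()} - set(GROUPS)
        if bad_groups:
            raise SpongenetError(f"unknown group labels: {sorted(bad_groups)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.group_labels[s] == group]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise SpongenetError(f"unknown gene ids requested: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.gene_class,
                                dict(self.group_labels))


@dataclass(frozen=True)
class Interaction:
    mirna: str
    target: str
    target_class: str


@dataclass
class InteractionSet:
    """Directed miRNA -> target pairs with a target class tag."""

    pairs: set[tuple[str, str, str]] = field(default_factory=set)
    provenance: str = ""

    def __post_init__(self) -> None:
        for p in self.pairs:
            if p[2] not in TARGET_CLASSES:
                raise SpongenetError(f"bad target class in pair {p}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str, str]) -> bool:
        return pair in self.pairs

    def mirnas(self) -> set[str]:
        return {m for m, _, _ in self.pairs}

    def targets(self, target_class: str | None = None) -> set[str]:
        return {t for _, t, c in self.pairs
                if target_class is None or c == target_class}

    def restrict(self, mirnas: Iterable[str] | None = None,
                 targets: Iterable[str] | None = None) -> "InteractionSet":
        ms = set(mirnas) if mirnas is not None else None
        ts = set(targets) if targets is not None else None
        kept = {p for p in self.pairs
                if (ms is None or p[0] in ms) and (ts is None or p[1] in ts)}
        return InteractionSet(kept, self.provenance)

    def union(self, other: "InteractionSet") -> "InteractionSet":
        return InteractionSet(self.pairs | other.pairs,
                              f"{self.provenance}+{other.provenance}")

    def regulators_of(self) -> dict[str, set[str]]:
        """Map target id -> set of miRNA regulators."""
        out: dict[str, set[str]] = {}
        for m, t, _ in self.pairs:
            out.setdefault(t, set()).add(m)
        return out

    def pairs_no_class(self) -> set[tuple[str, str]]:
        return {(m, t) for m, t, _ in self.pairs}


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline in one place.

    Defaults mirror the published protocol: top 100/300/4000 differential
    miRNA/lncRNA/mRNA, validation at K in {50,100,150,200}, sharing and
    correlation significance at 0.05, SC cutoff grid 0.1..0.3 step 0.05
    with 0.25 as the fall-back cutoff, top-20% hubs, bicliques and sponge
    modules of minimum size 3.
    """

    top_counts: dict[str, int] = field(
        default_factory=lambda: {"miRNA": 100, "lncRNA": 300, "mRNA": 4000})
    topk_list: list[int] = field(default_factory=lambda: [50, 100, 150, 200])
    network_k: int = 200
    sc_grid: tuple[float, float, float] = (0.1, 0.3, 0.05)
    p_share: float = 0.05
    p_corr: float = 0.05
    sc_cutoff: float | None = None       # None -> choose by cutoff scan
    min_shared_mirnas: int = 1
    mcl_inflation: float = 2.0
    hub_fraction: float = 0.2
    min_biclique_left: int = 3
    min_biclique_right: int = 3
    min_sponge_module_size: int = 3
    rng_seed: int = 0
    # method details
    rank_signed: bool = False            # False: rank by |statistic|
    mi_bins: int | None = None           # None -> max(2, floor(sqrt(n/5)))
    rdc_features: int = 20
    rdc_scale: float = 1.0 / 6.0
    cv_folds: int = 5
    enet_l1_ratio: float = 0.5
    ida_alpha: float = 0.05
    ida_max_cond: int = 3
    ida_var_budget: int = 100
    min_set_size: int = 5
    max_set_size: int = 5000
    # bookkeeping: inputs are assumed already log-scale/normalised
    assume_log_scale: bool = True

    def __post_init__(self) -> None:
        for name in ("p_share", "p_corr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise SpongenetError(f"{name} must be in (0,1), got {v}")
        if not 0 < self.hub_fraction <= 1:
            raise SpongenetError(f"hub_fraction must be in (0,1], got {self.hub_fraction}")
        low, high, step = self.sc_grid
        if not (low < high and step > 0):
            raise SpongenetError(f"bad sc_grid {self.sc_grid}")
        if self.mcl_inflation <= 1:
            raise SpongenetError("mcl_inflation must exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sc_grid" in raw:
            raw["sc_grid"] = tuple(raw["sc_grid"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["sc_grid"] = list(raw["sc_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_labels(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Two-column sample_id -> group TSV; preserves file order."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise SpongenetError(f"{path}: malformed label line {lineno}: {line!r}")
            sid, group = parts
            if lineno == 1 and group not in GROUPS:
                continue  # header row
            if group not in GROUPS:
                raise SpongenetError(
                    f"{path}: line {lineno}: group must be one of {GROUPS}, got {group!r}")
            if sid in labels:
                raise SpongenetError(f"{path}: duplicated sample id {sid!r}")
            labels[sid] = group
    return labels


def read_expression(path: str | Path, gene_class: str,
                    labels_path: str | Path, sep: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples table and align columns to label-file order.

    A sample present in the matrix but absent from the label file is a hard
    error; samples are reordered to the label file's order.
    """
    labels = read_labels(labels_path, sep=sep)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise SpongenetError(f"{path}: duplicated gene ids: {dups}")
    # convert cell by cell only on failure; fast path via astype
    try:
        num = df.astype(float)
    except ValueError:
        for gid, row in df.iterrows():
            for sid, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise SpongenetError(
                        f"{path}: non-numeric value {cell!r} at gene {gid!r}, "
                        f"sample {sid!r}") from None
        raise
    missing = [s for s in num.columns if s not in labels]
    if missing:
        raise SpongenetError(f"{path}: samples missing from labels: {missing}")
    order = [s for s in labels if s in set(num.columns)]
    num = num[order]
    return ExpressionMatrix(num, gene_class, {s: labels[s] for s in order})


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    expr.data.to_csv(path, sep=sep, index_label="gene_id",
                     float_format="%.17g")


def write_labels(labels: Mapping[str, str], path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for sid, group in labels.items():
            fh.write(f"{sid}{sep}{group}\n")


def read_interactions(path: str | Path, target_class: str,
                      sep: str = "\t") -> InteractionSet:
    """Two-column (miRNA, target) TSV; duplicates collapse to a set.

    A header row is tolerated: the first line is skipped when its fields
    reappear nowhere in the data column ids (heuristic on 'mirna'/'target'
    style names is avoided; non-overlap with the data is the criterion).
    """
    if target_class not in TARGET_CLASSES:
        raise SpongenetError(f"bad target class {target_class!r}")
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln]
    if not lines:
        logger.warning("%s: empty interaction file", path)
        return InteractionSet(set(), provenance=str(path))
    for lineno, line in enumerate(lines, 1):
        parts = line.split(sep)
        if len(parts) != 2:
            raise SpongenetError(f"{path}: malformed line {lineno}: {line!r}")
        rows.append((parts[0], parts[1]))
    if len(rows) > 1:
        head = rows[0]
        body_ids = {x for r in rows[1:] for x in r}
        if head[0] not in body_ids and head[1] not in body_ids:
            rows = rows[1:]
    pairs = {(m, t, target_class) for m, t in rows}
    return InteractionSet(pairs, provenance=str(path))


def write_interactions(interactions: InteractionSet, path: str | Path,
                       sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for m, t, _ in sorted(interactions.pairs):
            fh.write(f"{m}{sep}{t}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SpongenetError(f"{path}: malformed GMT line {lineno}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\t{description}\t{members}\n")


def write_edge_list(edges: Iterable[tuple[str, str, float]], path: str | Path,
                    header: tuple[str, str, str] = ("node1", "node2", "weight")) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_graphml(edges: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=float(w))
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# alignment and checksums
# ---------------------------------------------------------------------------

def align_samples(*matrices: ExpressionMatrix) -> tuple[ExpressionMatrix, ...]:
    """Restrict all matrices to their common samples, in a shared order.

    The order of the first matrix is kept.  Downstream correlation-based
    steps require this alignment; a matrix pair with no common samples is
    a hard error.
    """
    if not matrices:
        return ()
    common = [s for s in matrices[0].sample_ids
              if all(s in m.data.columns for m in matrices[1:])]
    if not common:
        raise SpongenetError("no common samples across expression matrices")
    out = []
    for m in matrices:
        out.append(ExpressionMatrix(m.data[common], m.gene_class,
                                    {s: m.group_labels[s] for s in common}))
    return tuple(out)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
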