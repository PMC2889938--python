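"""Core data containers for time-series expression and TF->gene networks.

Expression data are log2 ratios (sample over unstimulated reference) of
I genes sampled on a per-condition time grid; conditions are stimulus
doses (e.g. LPS 0.01/0.1/1 ug/ml) and columns of a merged matrix are the
concatenation of the per-condition grids.  The regulatory network is the
bipartite TF->gene edge set that fixes the support (nonzero pattern) of
the influence-strength matrix used by NCA.

File formats (plain TSV):
  expression: first column ``gene_id``; remaining headers ``<condition>@<time_h>``
  network:    columns ``tf_id  gene_id  [sign]``, ``#`` comments allowed
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "ExpressionMatrix",
    "RegulatoryNetwork",
    "ValidationError",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "filter_expressed",
    "concat_conditions",
]


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicates, NaN, mismatch)."""


class FormatError(ValueError):
    """File cannot be parsed as the expected TSV layout."""


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sampling times in hours, first >= 0, length >= 2."""

    times: tuple[float, ...]

    def __init__(self, times: Iterable[float]):
        t = tuple(float(x) for x in times)
        if len(t) < 2:
            raise ValidationError(f"time grid needs >= 2 points, got {len(t)}")
        if t[0] < 0:
            raise ValidationError(f"time grid starts at {t[0]} < 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError(f"time grid not strictly increasing: {t}")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.times)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


@dataclass
class ExpressionMatrix:
    """Genes x (condition, time) log2-ratio matrix with explicit grids.

    ``values`` has one row per gene and one column per (condition, time)
    pair, condition blocks in the order of ``conditions`` and times in
    grid order within each block.
    """

    gene_ids: list[str]
    conditions: list[str]
    grids: dict[str, TimeGrid]
    values: np.ndarray
    allow_nan: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError(f"duplicate condition labels: {self.conditions}")
        if set(self.conditions) != set(self.grids):
            raise ValidationError("conditions and grids keys differ")
        ncol = sum(len(self.grids[c]) for c in self.conditions)
        if self.values.shape != (len(self.gene_ids), ncol):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.gene_ids)}, {ncol}) implied by grids"
            )
        if not self.allow_nan and not np.all(np.isfinite(self.values)):
            bad = [self.gene_ids[i] for i in
                   sorted(set(np.argwhere(~np.isfinite(self.values))[:, 0].tolist()))]
            raise ValidationError(f"non-finite values in genes: {bad}")

    # -- column bookkeeping -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column_labels(self) -> list[tuple[str, float]]:
        """(condition, time) pair for every column, in column order."""
        out: list[tuple[str, float]] = []
        for c in self.conditions:
            out.extend((c, t) for t in self.grids[c].times)
        return out

    def condition_slice(self, condition: str) -> slice:
        """Column slice of one condition's block in the merged matrix."""
        start = 0
        for c in self.conditions:
            j = len(self.grids[c])
            if c == condition:
                return slice(start, start + j)
            start += j
        raise KeyError(condition)

    def condition_block(self, condition: str) -> np.ndarray:
        return self.values[:, self.condition_slice(condition)]

    def drop_nan_genes(self) -> "ExpressionMatrix":
        keep = np.all(np.isfinite(self.values), axis=1)
        return ExpressionMatrix(
            [g for g, k in zip(self.gene_ids, keep) if k],
            list(self.conditions), dict(self.grids), self.values[keep],
        )


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Bipartite TF->gene edges; sign +1 activation, -1 repression, 0 unknown."""

    tf_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]

    def __init__(self, tf_ids: Sequence[str], gene_ids: Sequence[str],
                 edges: Iterable[tuple[str, str, int]]):
        tfs = tuple(tf_ids)
        genes = tuple(gene_ids)
        el = tuple((str(t), str(g), int(s)) for t, g, s in edges)
        if len(set(tfs)) != len(tfs):
            raise ValidationError("duplicate tf ids")
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate gene ids")
        pairs = [(t, g) for t, g, _ in el]
        if len(set(pairs)) != len(pairs):
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ValidationError(f"duplicate (tf, gene) edges: {dupes}")
        tfset, geneset = set(tfs), set(genes)
        for t, g, s in el:
            if t not in tfset:
                raise ValidationError(f"edge references undeclared TF {t!r}")
            if g not in geneset:
                raise ValidationError(f"edge references undeclared gene {g!r}")
            if s not in (-1, 0, 1):
                raise ValidationError(f"edge sign {s} not in {{-1,0,1}}")
        touched_tfs = {t for t, _, _ in el}
        touched_genes = {g for _, g, _ in el}
        if tfset - touched_tfs:
            raise ValidationError(f"TFs without edges: {sorted(tfset - touched_tfs)}")
        if geneset - touched_genes:
            raise ValidationError(
                f"genes without edges: {sorted(geneset - touched_genes)}")
        object.__setattr__(self, "tf_ids", tfs)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "edges", el)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def support(self, gene_order: Sequence[str] | None = None) -> np.ndarray:
        """Boolean I x K mask of regulated (gene, TF) pairs.

        Rows follow ``gene_order`` when given (genes absent from the
        network get an all-False row), else the network's own gene order.
        """
        genes = list(gene_order) if gene_order is not None else list(self.gene_ids)
        gidx = {g: i for i, g in enumerate(genes)}
        kidx = {t: k for k, t in enumerate(self.tf_ids)}
        mask = np.zeros((len(genes), len(self.tf_ids)), dtype=bool)
        for t, g, _ in self.edges:
            if g in gidx:
                mask[gidx[g], kidx[t]] = True
        return mask

    def regulon(self, tf: str) -> list[str]:
        if tf not in self.tf_ids:
            raise KeyError(f"unknown TF {tf!r}")
        return [g for t, g, _ in self.edges if t == tf]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_column_header(tok: str) -> tuple[str, float]:
    if "@" not in tok:
        raise FormatError(f"column header {tok!r} lacks '<condition>@<time_h>' form")
    cond, _, t = tok.rpartition("@")
    if not cond:
        raise FormatError(f"column header {tok!r} has empty condition")
    try:
        return cond, float(t)
    except ValueError:
        raise FormatError(f"unparseable time token {t!r} in header {tok!r}") from None


def read_expression(path, *, allow_nan: bool = False) -> ExpressionMatrix:
    """Read a wide TSV (``gene_id`` + ``cond@time`` columns) into a matrix.

    Row order is preserved from the file; condition order follows first
    appearance in the header.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id plus >= 1 data column")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df.isna().all(axis=1).any():
        raise FormatError(f"{path}: blank or ragged row present")
    parsed = [_parse_column_header(c) for c in df.columns[1:]]
    conditions: list[str] = []
    times: dict[str, list[float]] = {}
    for cond, t in parsed:
        if cond not in times:
            conditions.append(cond)
            times[cond] = []
        times[cond].append(t)
    # columns must be grouped by condition, times increasing within each
    expect = [(c, t) for c in conditions for t in times[c]]
    if parsed != expect:
        raise FormatError(f"{path}: columns not grouped by condition")
    grids = {c: TimeGrid(ts) for c, ts in times.items()}
    genes = df.iloc[:, 0].tolist()
    try:
        vals = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from None
    return ExpressionMatrix(genes, conditions, grids, vals, allow_nan=allow_nan)


def write_expression(expr: ExpressionMatrix, path) -> None:
    cols = ["gene_id"] + [
        f"{c}@{t:g}" for c, t in expr.column_labels()
    ]
    df = pd.DataFrame(
        np.column_stack([np.array(expr.gene_ids, dtype=object), expr.values]),
        columns=cols,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_network(path) -> RegulatoryNetwork:
    """Read a 2/3-column TSV edge list; missing sign column means sign 0."""
    edges: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise FormatError(f"{path}:{ln}: expected 2 or 3 columns, got {len(parts)}")
            tf, gene = parts[0].strip(), parts[1].strip()
            if not tf or not gene:
                raise FormatError(f"{path}:{ln}: empty tf or gene field")
            sign = 0
            if len(parts) == 3 and parts[2].strip():
                try:
                    sign = int(parts[2])
                except ValueError:
                    raise FormatError(f"{path}:{ln}: bad sign {parts[2]!r}") from None
            key = (tf, gene)
            if key in edges:
                if edges[key] != sign:
                    raise FormatError(
                        f"{path}:{ln}: conflicting signs for edge {tf}->{gene}")
                continue
            edges[key] = sign
    tfs = list(dict.fromkeys(t for t, _ in edges))
    genes = list(dict.fromkeys(g for _, g in edges))
    return RegulatoryNetwork(tfs, genes, [(t, g, s) for (t, g), s in edges.items()])


def write_network(net: RegulatoryNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# tf_id\tgene_id\tsign\n")
        for t, g, s in net.edges:
            fh.write(f"{t}\t{g}\t{s:+d}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_expressed(
    expr: ExpressionMatrix,
    net: RegulatoryNetwork,
    min_abs_logratio: float = 1.0,
) -> tuple[ExpressionMatrix, RegulatoryNetwork]:
    """Drop genes never exceeding ``min_abs_logratio`` in magnitude.

    Mirrors the pre-NCA step of removing target genes without a
    significant stimulus response.  Edges of removed genes are dropped
    and TFs left without edges disappear; the default 1.0 log2 unit is a
    two-fold change.
    """
    if min_abs_logratio < 0:
        raise ValidationError("threshold must be >= 0")
    keep = np.max(np.abs(expr.values), axis=1) >= min_abs_logratio
    if not keep.any():
        raise ValidationError("filter removed every gene (empty model)")
    kept_genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    sub = ExpressionMatrix(kept_genes, list(expr.conditions), dict(expr.grids),
                           expr.values[keep])
    kept_set = set(kept_genes)
    edges = [(t, g, s) for t, g, s in net.edges if g in kept_set]
    tfs = [t for t in net.tf_ids if any(e[0] == t for e in edges)]
    genes = [g for g in net.gene_ids if g in kept_set and any(e[1] == g for e in edges)]
    if not edges:
        raise ValidationError("filter removed every network edge")
    return sub, RegulatoryNetwork(tfs, genes, edges)


def concat_conditions(exprs: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge per-condition matrices into one expanded matrix, aligning genes.

    All inputs must cover the same gene set; rows are aligned to the
    first input's order.  Condition labels must be disjoint.
    """
    if not exprs:
        raise ValidationError("no matrices to concatenate")
    if len(exprs) == 1:
        e = exprs[0]
        return ExpressionMatrix(list(e.gene_ids), list(e.conditions),
                                dict(e.grids), e.values.copy())
    ref = exprs[0]
    ref_set = set(ref.gene_ids)
    for e in exprs[1:]:
        if set(e.gene_ids) != ref_set:
            diff = sorted(ref_set ^ set(e.gene_ids))
            raise ValidationError(f"gene sets differ; symmetric difference: {diff}")
    conditions: list[str] = []
    grids: dict[str, TimeGrid] = {}
    blocks = []
    for e in exprs:
        for c in e.conditions:
            if c in grids:
                raise ValidationError(f"condition label {c!r} repeated across inputs")
            conditions.append(c)
            grids[c] = e.grids[c]
        idx = [e.gene_ids.index(g) for g in ref.gene_ids]
        blocks.append(e.values[idx])
    return ExpressionMatrix(list(ref.gene_ids), conditions, grids,
                            np.hstack(blocks))
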