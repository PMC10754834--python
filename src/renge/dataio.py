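"""Input/output for expression matrices, cell metadata, edge tables and fitted models.

The in-memory containers here are the single source of truth for gene
ordering: every matrix-valued object downstream (network coefficients,
knockdown vectors, truth adjacencies) indexes genes exactly as
``ExpressionDataset.gene_names`` does.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

#: Sentinel KO label for unperturbed (wild-type / non-targeting) cells.
#: Matched case-insensitively on input; "ctrl" and "wt" are accepted aliases.
CONTROL = "control"

_CONTROL_ALIASES = {"control", "ctrl", "wt", "wildtype", "wild-type", "non-targeting"}


class FormatError(ValueError):
    """Raised when an input file does not match its declared shape/schema."""


@dataclass
class ExpressionDataset:
    """Normalized cells x genes expression with per-cell time and KO annotations.

    Attributes
    ----------
    expr
        (n_cells, n_genes) array of normalized expression values.
    gene_names
        Ordered gene identifiers (columns of ``expr``).
    cell_ids
        Ordered unique cell identifiers (rows of ``expr``).
    time_index
        Per-cell sampling time remapped to contiguous integers 1..T.
    ko_gene
        Per-cell KO target gene name, or :data:`CONTROL`.
    perturb_prob
        Per-cell probability that the detected gRNA actually perturbed the
        transcriptome; 1.0 by default for KO cells, ignored for controls.
    time_labels
        Mapping from internal contiguous time index to the raw input label
        (e.g. {1: 2, 2: 3, ...} when sampling days were 2..5).
    """

    expr: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    time_index: np.ndarray
    ko_gene: np.ndarray
    perturb_prob: np.ndarray | None = None
    time_labels: dict[int, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.gene_names = list(map(str, self.gene_names))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.expr.shape != (len(self.cell_ids), len(self.gene_names)):
            raise FormatError(
                f"expression shape {self.expr.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_names)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell_ids")
        self.time_index = np.asarray(self.time_index, dtype=int)
        self.ko_gene = np.asarray(self.ko_gene, dtype=object)
        if self.perturb_prob is None:
            self.perturb_prob = np.ones(self.n_cells)
        self.perturb_prob = np.asarray(self.perturb_prob, dtype=float)
        unknown = {
            g for g in self.ko_gene if g != CONTROL and g not in set(self.gene_names)
        }
        if unknown:
            raise FormatError(f"ko_gene labels not in gene_names: {sorted(unknown)}")

    # -- basic views ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_times(self) -> int:
        return int(self.time_index.max())

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.time_index)

    @property
    def ko_genes(self) -> list[str]:
        """Sorted unique KO target genes (controls excluded)."""
        return sorted({g for g in self.ko_gene if g != CONTROL})

    @property
    def is_control(self) -> np.ndarray:
        return self.ko_gene == CONTROL

    def gene_index(self, gene: str) -> int:
        return self.gene_names.index(gene)

    def strata(self):
        """Yield ((ko_gene, time), cell index array) for every stratum."""
        for g in [CONTROL] + self.ko_genes:
            for t in self.times:
                idx = np.flatnonzero((self.ko_gene == g) & (self.time_index == t))
                if idx.size:
                    yield (g, int(t)), idx

    def subset(self, indices: np.ndarray, suffix: str = "") -> "ExpressionDataset":
        """Row-subset (with possible repeats); ``suffix``+position disambiguates ids."""
        indices = np.asarray(indices, dtype=int)
        if suffix:
            ids = [f"{self.cell_ids[i]}{suffix}{k}" for k, i in enumerate(indices)]
        else:
            ids = [self.cell_ids[i] for i in indices]
        return ExpressionDataset(
            expr=self.expr[indices],
            gene_names=self.gene_names,
            cell_ids=ids,
            time_index=self.time_index[indices],
            ko_gene=self.ko_gene[indices],
            perturb_prob=self.perturb_prob[indices],
            time_labels=dict(self.time_labels),
        )

    def fingerprint(self) -> str:
        """Order-insensitive hash of (cell_id, time, ko) triples, for leak checks."""
        items = sorted(zip(self.cell_ids, self.time_index.tolist(), self.ko_gene.tolist()))
        return str(hash(tuple(items)))


@dataclass
class TruthNetwork:
    """Ground-truth adjacency; entry (i, j) refers to regulation j -> i.

    ``scores`` (optional) carries real-valued confidences (e.g. binding
    significance scores) from which ``adjacency`` was thresholded;
    ``signs`` (optional) carries {-1, 0, +1} regulation signs.
    """

    adjacency: np.ndarray
    gene_names: list[str]
    scores: np.ndarray | None = None
    signs: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        G = len(self.gene_names)
        if self.adjacency.shape != (G, G):
            raise FormatError("truth adjacency must be G x G")
        np.fill_diagonal(self.adjacency, False)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edge_list(self) -> pd.DataFrame:
        tgt, reg = np.nonzero(self.adjacency)
        return pd.DataFrame(
            {
                "regulator": [self.gene_names[j] for j in reg],
                "target": [self.gene_names[i] for i in tgt],
            }
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_index_file(path: Path) -> list[str]:
    # one identifier per line; extra tab-separated columns (10x style) ignored
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                names.append(line.split("\t")[0].split(",")[0])
    return names


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read a cells x genes expression matrix.

    Two layouts are supported:

    * dense delimited text (comma or tab, auto-detected from the header):
      first column cell ids, header row gene names;
    * Matrix Market triplet (``.mtx``) in the genes x cells orientation
      used by droplet pipelines, with companion ``genes_path`` /
      ``cells_path`` index files (one identifier per line).

    The returned dataset has placeholder time/KO annotations; call
    :func:`read_metadata` to complete it.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise FormatError("mtx input requires genes_path and cells_path")
        raw = mmread(matrix_path)
        mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        genes = _read_index_file(Path(genes_path))
        cells = _read_index_file(Path(cells_path))
        if mat.shape == (len(genes), len(cells)):
            mat = mat.T
        elif mat.shape != (len(cells), len(genes)):
            axis = "gene" if mat.shape[0] != len(genes) and mat.shape[1] != len(genes) else "cell"
            raise FormatError(
                f"matrix shape {mat.shape} incompatible with {len(genes)} genes "
                f"x {len(cells)} cells (offending axis: {axis})"
            )
        expr, gene_names, cell_ids = mat, genes, cells
    else:
        df = pd.read_csv(matrix_path, sep=_detect_sep(matrix_path), index_col=0)
        expr = df.to_numpy(dtype=float)
        gene_names = [str(c) for c in df.columns]
        cell_ids = [str(i) for i in df.index]

    if expr.size and np.all(expr >= 0) and np.allclose(expr, np.round(expr)):
        warnings.warn(
            "expression matrix contains only nonnegative integers; input may be "
            "raw counts — the model expects normalized expression",
            UserWarning,
            stacklevel=2,
        )
    n = len(cell_ids)
    return ExpressionDataset(
        expr=expr,
        gene_names=gene_names,
        cell_ids=cell_ids,
        time_index=np.ones(n, dtype=int),
        ko_gene=np.array([CONTROL] * n, dtype=object),
    )


def read_metadata(meta_path: str | Path, dataset: ExpressionDataset) -> ExpressionDataset:
    """Join per-cell metadata (cell_id, time, ko_gene[, perturb_prob]) onto a dataset.

    Raw time labels (e.g. sampling days 2..5) are rank-remapped to contiguous
    integers 1..T; the original labels are kept in ``time_labels``. The
    control sentinel is matched case-insensitively.
    """
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path, sep=_detect_sep(meta_path))
    required = {"cell_id", "time", "ko_gene"}
    if not required.issubset(meta.columns):
        raise FormatError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index(meta["cell_id"].astype(str))
    missing = [c for c in dataset.cell_ids if c not in meta.index]
    if missing:
        raise FormatError(f"cells missing from metadata: {missing[:5]}" +
                          (f" (+{len(missing)-5} more)" if len(missing) > 5 else ""))
    meta = meta.loc[dataset.cell_ids]

    raw_time = meta["time"].to_numpy()
    levels = sorted(pd.unique(raw_time).tolist())
    remap = {lab: i + 1 for i, lab in enumerate(levels)}
    time_index = np.array([remap[v] for v in raw_time], dtype=int)
    time_labels = {i + 1: lab for i, lab in enumerate(levels)}

    ko_raw = meta["ko_gene"].astype(str)
    ko = np.array(
        [CONTROL if g.lower() in _CONTROL_ALIASES else g for g in ko_raw],
        dtype=object,
    )
    known = set(dataset.gene_names)
    unknown = sorted({g for g in ko if g != CONTROL and g not in known})
    if unknown:
        raise FormatError(f"ko_gene labels not in gene_names: {unknown}")

    if "perturb_prob" in meta.columns:
        pc = meta["perturb_prob"].astype(float).to_numpy()
        pc = np.where(np.isnan(pc), 1.0, pc)
    else:
        pc = np.ones(dataset.n_cells)
    return ExpressionDataset(
        expr=dataset.expr,
        gene_names=dataset.gene_names,
        cell_ids=dataset.cell_ids,
        time_index=time_index,
        ko_gene=ko,
        perturb_prob=pc,
        time_labels=time_labels,
    )


# ---------------------------------------------------------------------------
# edge tables
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["regulator", "target", "coefficient", "p_value", "q_value"]


def sort_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Canonical edge ordering: descending |coefficient|, ties broken
    lexicographically by regulator then target."""
    df = edges.copy()
    df["_abs"] = df["coefficient"].abs()
    df = df.sort_values(
        ["_abs", "regulator", "target"], ascending=[False, True, True], kind="mergesort"
    ).drop(columns="_abs")
    return df.reset_index(drop=True)


def write_edge_table(edges: pd.DataFrame, out_path: str | Path) -> None:
    """Write a tab-delimited edge table in canonical order."""
    df = edges.reindex(columns=EDGE_COLUMNS)
    sort_edges(df).to_csv(out_path, sep="\t", index=False)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_truth(
    path: str | Path,
    gene_names: list[str],
    score_col: str = "score",
    threshold: float | None = None,
) -> TruthNetwork:
    """Read a ground-truth network from an edge list or score table.

    The file needs ``regulator`` and ``target`` columns; an optional score
    column (thresholded at ``threshold`` with strict >) and an optional
    ``sign`` column are used when present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    if not {"regulator", "target"}.issubset(df.columns):
        raise FormatError("truth table must have regulator and target columns")
    G = len(gene_names)
    gi = {g: i for i, g in enumerate(gene_names)}
    adjacency = np.zeros((G, G), dtype=bool)
    scores = np.full((G, G), np.nan) if score_col in df.columns else None
    signs = np.zeros((G, G)) if "sign" in df.columns else None
    for _, row in df.iterrows():
        r, t = str(row["regulator"]), str(row["target"])
        if r not in gi or t not in gi:
            continue
        i, j = gi[t], gi[r]
        s = float(row[score_col]) if score_col in df.columns else None
        if scores is not None:
            scores[i, j] = s
        present = True if s is None or threshold is None else s > threshold
        adjacency[i, j] = present
        if signs is not None:
            signs[i, j] = float(np.sign(row["sign"]))
    return TruthNetwork(
        adjacency=adjacency, gene_names=gene_names, scores=scores,
        signs=signs, threshold=threshold,
    )


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def write_model(model, out_path: str | Path) -> None:
    """Serialize a fitted model (see :class:`renge.core.GRNModel`) to JSON."""
    payload = {
        "gene_names": model.gene_names,
        "A": model.A.tolist(),
        "b": model.b.tolist(),
        "alpha": model.alpha,
        "beta_w": model.beta_w,
        "gamma_w": model.gamma_w,
        "K": model.K,
        "lambda1": model.lambda1,
        "lambda2": model.lambda2,
        "fixed_weight": model.fixed_weight,
        "converged": bool(model.converged),
        "seed": model.seed,
    }
    with open(out_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_model(path: str | Path):
    from .core import GRNModel

    with open(path) as fh:
        d = json.load(fh)
    return GRNModel(
        A=np.asarray(d["A"], dtype=float),
        b=np.asarray(d["b"], dtype=float),
        alpha={k: float(v) for k, v in d["alpha"].items()},
        beta_w=float(d["beta_w"]),
        gamma_w=float(d["gamma_w"]),
        K=int(d["K"]),
        lambda1=float(d["lambda1"]),
        lambda2=float(d["lambda2"]),
        gene_names=list(d["gene_names"]),
        fixed_weight=d.get("fixed_weight"),
        converged=bool(d.get("converged", True)),
        seed=d.get("seed"),
    )
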