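"""Matrix I/O, standardization, and similarity-based feature ordering.

File orientation is fixed throughout: samples in rows, features in columns;
the header row holds feature identifiers and the first column sample
identifiers.  Delimiter is inferred from the extension (.csv -> comma,
anything else tab) and can be overridden.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix
from .f1 import Bicluster

__all__ = ["read_matrix", "write_matrix", "standardize", "order_features",
           "write_biclusters", "read_biclusters"]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Parse a samples x features TSV/CSV into an :class:`ExpressionMatrix`."""
    path = Path(path)
    sep_ = _sep_for(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep_)[1:]
    df = pd.read_csv(path, sep=sep_, index_col=0)
    if df.index.has_duplicates or len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate sample or feature identifiers")
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
    return ExpressionMatrix(df.to_numpy(dtype=float),
                            sample_ids=[str(i) for i in df.index],
                            feature_ids=[str(c) for c in df.columns])


def write_matrix(M: ExpressionMatrix, path: str | Path,
                 sep: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(M.values, index=M.sample_ids, columns=M.feature_ids)
    df.to_csv(path, sep=_sep_for(path, sep))


def standardize(M: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature (column) centering and scaling to unit sample variance."""
    mean = M.values.mean(axis=0)
    sd = M.values.std(axis=0, ddof=1) if M.n > 1 else np.zeros(M.p)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance feature {M.feature_ids[int(zero[0])]!r}; "
            "remove constant features before standardizing")
    return ExpressionMatrix((M.values - mean) / sd,
                            sample_ids=list(M.sample_ids),
                            feature_ids=list(M.feature_ids),
                            feature_order=M.feature_order.copy())


def order_features(M: ExpressionMatrix,
                   similarity: np.ndarray) -> ExpressionMatrix:
    """Greedy nearest-neighbour seriation of the features.

    Starts from the most similar feature pair and repeatedly appends the
    unplaced feature most similar to the current path endpoint.  The
    similarity matrix (e.g., a GO semantic similarity computed upstream) must
    be symmetric with maximal diagonal; only the resulting permutation is
    kept, recorded in ``feature_order``.
    """
    sim = np.asarray(similarity, dtype=float)
    p = M.p
    if sim.shape != (p, p):
        raise ValueError(f"similarity matrix must be {p}x{p}")
    if not np.allclose(sim, sim.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    if p == 1:
        return M

    off = sim.copy()
    np.fill_diagonal(off, -np.inf)
    a, b = np.unravel_index(np.argmax(off), off.shape)
    order = [int(a), int(b)]
    placed = np.zeros(p, dtype=bool)
    placed[[a, b]] = True
    while len(order) < p:
        scores = np.where(placed, -np.inf, sim[order[-1]])
        nxt = int(np.argmax(scores))
        order.append(nxt)
        placed[nxt] = True

    perm = np.asarray(order)
    return ExpressionMatrix(M.values[:, perm],
                            sample_ids=list(M.sample_ids),
                            feature_ids=[M.feature_ids[j] for j in perm],
                            feature_order=perm)


def write_biclusters(biclusters: list[Bicluster], path: str | Path) -> None:
    """TSV with one row per member: cluster id, state label, member type, id."""
    rows = []
    for idx, bc in enumerate(biclusters):
        cluster, state = divmod(idx, 3)
        for s in sorted(bc.samples):
            rows.append((cluster + 1, state + 1, "sample", s))
        for f in sorted(bc.features):
            rows.append((cluster + 1, state + 1, "feature", f))
    pd.DataFrame(rows, columns=["cluster", "state", "member_type", "member"]) \
        .to_csv(path, sep="\t", index=False)


def read_biclusters(path: str | Path) -> list[Bicluster]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (_, _), grp in df.groupby(["cluster", "state"], sort=True):
        out.append(Bicluster(
            samples=grp.loc[grp.member_type == "sample", "member"].astype(int),
            features=grp.loc[grp.member_type == "feature", "member"].astype(int)))
    return out


def write_truth(truth, path: str | Path) -> None:
    """Sidecar JSON for simulated data ground truth."""
    payload = {
        "z_true": truth.z_true.tolist(),
        "rho_true": truth.rho_true.tolist(),
        "mu_true": truth.mu_true.tolist(),
        "sigma2_true": truth.sigma2_true,
        "setting": truth.setting,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload))
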