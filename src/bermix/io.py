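"""Reading and writing count tables, labels, parameters and predictions.

Count tables are plain TSV/CSV with identifiers in the first row and column.
Parameters round-trip through JSON at full float precision; all derived
tables are written as TSV.  Orientation (samples in rows vs. taxa in rows)
is never guessed: the caller states it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .model import CountData, ModelParameters

__all__ = [
    "read_count_table",
    "read_labels",
    "attach_labels",
    "top_taxa",
    "write_params",
    "read_params",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_table(
    path, orientation: str = "samples", drop_zero_samples: bool = False
) -> CountData:
    """Read a delimited count table into a :class:`CountData` (labels all 0).

    ``orientation`` is ``"samples"`` (samples in rows) or ``"taxa"`` (taxa in
    rows; the table is transposed on read).  Negative, missing or
    non-integer cells raise with the offending row and column named.
    Samples whose counts sum to zero raise unless ``drop_zero_samples``.
    """
    path = Path(path)
    if orientation not in ("samples", "taxa"):
        raise InvalidInputError("orientation must be 'samples' or 'taxa'")
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:
        raise InvalidInputError(f"could not parse {path}: {exc}") from exc
    if orientation == "taxa":
        df = df.T
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise InvalidInputError(f"duplicate identifiers in {path}")
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    problem = ~np.isfinite(arr) | (arr < 0) | (arr != np.floor(arr))
    if problem.any():
        r, c = np.argwhere(problem)[0]
        raise InvalidInputError(
            f"invalid cell at sample {df.index[r]!r}, taxon {df.columns[c]!r} "
            f"in {path}: must be a nonnegative integer"
        )
    counts = arr.astype(np.int64)
    keep = counts.sum(axis=1) > 0
    if not keep.all():
        zero_ids = list(df.index[~keep])
        if not drop_zero_samples:
            raise InvalidInputError(
                f"samples with zero total counts: {zero_ids}; "
                "pass drop_zero_samples=True (CLI: --drop-zero-samples) to drop them"
            )
        df = df.loc[keep]
        counts = counts[keep]
    return CountData(
        sample_ids=list(df.index.astype(str)),
        taxon_ids=list(df.columns.astype(str)),
        counts=counts,
        labels=np.zeros(len(df), dtype=np.int64),
    )


def read_labels(path) -> pd.Series:
    """Read a two-column (sample_id, label) file into a {0,1} Series."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] != 2:
        raise InvalidInputError(
            f"{path} must have exactly two columns (sample_id, label)"
        )
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dups = sorted(set(ids[ids.duplicated()]))
        raise InvalidInputError(f"duplicate sample ids in {path}: {dups}")
    labels = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if labels.isna().any() or not labels.isin([0, 1]).all():
        raise InvalidInputError(f"labels in {path} must be 0 or 1")
    return pd.Series(labels.astype(np.int64).to_numpy(), index=ids.to_numpy())


def attach_labels(data: CountData, labels: pd.Series) -> CountData:
    """Join labels to counts by sample id; unmatched ids on either side raise."""
    missing = [s for s in data.sample_ids if s not in labels.index]
    extra = [s for s in labels.index if s not in data.sample_ids]
    if missing or extra:
        raise InvalidInputError(
            f"label/count sample-id mismatch: missing labels for {missing}, "
            f"labels without counts for {extra}"
        )
    return CountData(
        sample_ids=data.sample_ids,
        taxon_ids=data.taxon_ids,
        counts=data.counts,
        labels=labels.loc[data.sample_ids].to_numpy(),
    )


def top_taxa(data: CountData, k: int) -> CountData:
    """Keep the k taxa with the largest mean relative abundance.

    Relative abundance is ``w_nk / M_n`` averaged over samples.  Ties at the
    cutoff break toward the lexicographically smaller taxon id; retained
    columns are ordered by descending mean abundance.  Totals are recomputed
    from the surviving columns.
    """
    if not 1 <= k <= data.n_taxa:
        raise InvalidInputError(f"k must be in [1, {data.n_taxa}], got {k}")
    rel = data.counts / data.totals[:, None]
    mean_rel = rel.mean(axis=0)
    order = sorted(
        range(data.n_taxa), key=lambda j: (-mean_rel[j], data.taxon_ids[j])
    )
    keep = order[:k]
    return CountData(
        sample_ids=data.sample_ids,
        taxon_ids=[data.taxon_ids[j] for j in keep],
        counts=data.counts[:, keep],
        labels=data.labels,
    )


def write_params(params: ModelParameters, path, taxon_ids=None) -> None:
    """Serialize parameters as JSON at full float precision."""
    payload = {
        "L": int(params.n_clusters),
        "K": int(params.n_taxa),
        "gamma": params.gamma,
        "phi": params.phi.tolist(),
        "rho": params.rho.tolist(),
        "P": params.P.tolist(),
        "cluster_order": "rho-ascending",
    }
    if taxon_ids is not None:
        payload["taxon_ids"] = list(taxon_ids)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_params(path) -> tuple[ModelParameters, list[str] | None]:
    """Inverse of :func:`write_params`; returns (params, taxon_ids or None)."""
    payload = json.loads(Path(path).read_text())
    params = ModelParameters(
        phi=np.asarray(payload["phi"]),
        rho=np.asarray(payload["rho"]),
        P=np.asarray(payload["P"]),
        gamma=float(payload.get("gamma", 0.0)),
    )
    return params, payload.get("taxon_ids")


def write_count_table(data: CountData, path) -> None:
    """Write counts as a samples-in-rows TSV/CSV table."""
    path = Path(path)
    pd.DataFrame(
        data.counts, index=data.sample_ids, columns=data.taxon_ids
    ).to_csv(path, sep=_sep_for(path), index_label="sample_id")


def write_labels(data: CountData, path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"sample_id": data.sample_ids, "label": data.labels}
    ).to_csv(path, sep=_sep_for(path), index=False)
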