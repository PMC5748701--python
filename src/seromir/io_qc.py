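"""Tabular I/O, validation and descriptive QC statistics.

Formats
-------
- count matrix: TSV (first column ``feature_id``, one column per sample)
  or MatrixMarket coordinate format with ``.rownames``/``.colnames``
  sidecar files (one id per line);
- sample sheet: TSV with columns sample_id, condition {case|control},
  family1 {0,1}, family2 {0,1}, absorbance_414;
- read-length histogram: TSV with columns sample_id, length, n_reads;
- precursor score table: TSV with columns cutoff, n_reported, fp_mean.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

DEFAULT_LENGTH_WINDOWS = ((21, 24), (29, 33))

#: floor on the mean false-positive count when forming signal-to-noise
#: ratios, so that zero-FP cutoffs count as arbitrarily clean
SNR_EPS = 1e-9


class ParseError(ValueError):
    """A file violates the format contract (named row/column in message)."""


def validate_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Check count-matrix invariants; returns the (integer-cast) matrix."""
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ParseError(f"duplicated feature id: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ParseError(f"duplicated sample id: {dup!r}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError("count matrix contains non-numeric entries")
    if np.isnan(values.astype(float)).any():
        i, j = np.argwhere(np.isnan(values.astype(float)))[0]
        raise ParseError(
            f"missing count at feature {counts.index[i]!r}, sample {counts.columns[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ParseError(
            f"negative count at feature {counts.index[i]!r}, sample {counts.columns[j]!r}"
        )
    if not np.allclose(values, np.round(values)):
        i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ParseError(
            f"non-integer count at feature {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}"
        )
    out = counts.astype(np.int64)
    out.index.name = "feature_id"
    return out


def read_count_matrix(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a validated feature x sample count matrix (TSV or MTX)."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx":
        mat = spio.mmread(str(path))
        rownames = Path(str(path) + ".rownames").read_text().split()
        colnames = Path(str(path) + ".colnames").read_text().split()
        arr = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        if arr.shape != (len(rownames), len(colnames)):
            raise ParseError(
                f"matrix shape {arr.shape} inconsistent with sidecars "
                f"({len(rownames)} rows, {len(colnames)} cols)"
            )
        df = pd.DataFrame(arr, index=rownames, columns=colnames)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")
    return validate_count_matrix(df)


def write_count_matrix(
    counts: pd.DataFrame, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        counts.rename_axis("feature_id").to_csv(path, sep="\t")
    elif format == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(counts.to_numpy()))
        Path(str(path) + ".rownames").write_text("\n".join(counts.index) + "\n")
        Path(str(path) + ".colnames").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")


REQUIRED_META_COLUMNS = ("sample_id", "condition", "family1", "family2", "absorbance_414")


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"sample sheet missing required column(s): {missing}")
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicated sample id: {dup!r}")
    cond = meta["condition"].astype(str).str.strip().str.lower()
    bad = ~cond.isin(["case", "control"])
    if bad.any():
        raise ParseError(
            f"unknown condition label {meta.loc[bad, 'condition'].iloc[0]!r} "
            f"for sample {meta.loc[bad, 'sample_id'].iloc[0]!r}"
        )
    meta["condition"] = cond
    for col in ("family1", "family2"):
        vals = meta[col].astype(int)
        if not vals.isin([0, 1]).all():
            raise ParseError(f"column {col!r} must be 0/1")
        meta[col] = vals
    both = (meta["family1"] == 1) & (meta["family2"] == 1)
    if both.any():
        raise ParseError(
            f"sample {meta.loc[both, 'sample_id'].iloc[0]!r} assigned to both "
            "family1 and family2 (cohorts are mutually exclusive)"
        )
    if (meta["absorbance_414"].astype(float) <= 0).any():
        bad_id = meta.loc[meta["absorbance_414"].astype(float) <= 0, "sample_id"].iloc[0]
        raise ParseError(f"non-positive absorbance_414 for sample {bad_id!r}")
    meta["absorbance_414"] = meta["absorbance_414"].astype(float)
    return meta.set_index("sample_id", drop=False)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet TSV (condition is case-insensitive)."""
    return validate_sample_metadata(pd.read_csv(Path(path), sep="\t"))


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(Path(path), sep="\t", index=False)


def read_length_histograms(path: str | Path) -> dict[str, pd.Series]:
    """Read per-sample read-length histograms (sample_id, length, n_reads)."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in ("sample_id", "length", "n_reads") if c not in df.columns]
    if missing:
        raise ParseError(f"read-length table missing column(s): {missing}")
    out = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        out[str(sid)] = pd.Series(
            grp["n_reads"].to_numpy(),
            index=pd.Index(grp["length"].to_numpy(), name="length"),
            name="n_reads",
        )
    return out


def write_length_histograms(hists: dict[str, pd.Series], path: str | Path) -> None:
    rows = []
    for sid, h in hists.items():
        for length, n in h.items():
            rows.append({"sample_id": sid, "length": int(length), "n_reads": int(n)})
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in ("cutoff", "n_reported", "fp_mean") if c not in df.columns]
    if missing:
        raise ParseError(f"score table missing column(s): {missing}")
    if (df["fp_mean"] < 0).any():
        raise ParseError("fp_mean must be >= 0")
    return df


def summarize_read_lengths(
    hist: pd.Series,
    windows: tuple[tuple[int, int], ...] = DEFAULT_LENGTH_WINDOWS,
) -> tuple[float, ...]:
    """Fraction of reads with length inside each inclusive window."""
    if hist.empty or hist.sum() <= 0:
        raise ValueError("read-length histogram is empty")
    lengths = hist.index.to_numpy()
    total = float(hist.sum())
    fractions = []
    for lo, hi in windows:
        mask = (lengths >= lo) & (lengths <= hi)
        fractions.append(float(hist.to_numpy()[mask].sum()) / total)
    return tuple(fractions)


def top_expression_fractions(
    counts: pd.DataFrame, size_factors: pd.Series, k: int
) -> tuple[pd.Series, float]:
    """Shares of normalized total counts held by the top-k features.

    Returns the descending per-feature shares and their cumulative sum.
    A dominant circulating miRNA typically carries most of a serum
    library, so the top-1 share is the headline QC number.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > counts.shape[0]:
        raise ValueError(f"k={k} exceeds number of features {counts.shape[0]}")
    sf = size_factors.reindex(counts.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    norm_totals = (counts / sf).sum(axis=1)
    shares = (norm_totals / norm_totals.sum()).sort_values(ascending=False)
    top = shares.iloc[:k]
    return top, float(top.sum())


def select_score_cutoff(
    table: pd.DataFrame, min_snr: float = 9.0, min_tp_rate: float = 0.8
) -> float | None:
    """Smallest score cutoff with adequate signal-to-noise and TP rate.

    For each cutoff t: SNR(t) = n_reported / max(fp_mean, eps) and
    TP(t) = (n_reported - fp_mean) / n_reported.  Returns the smallest
    cutoff satisfying both ``min_snr`` and ``min_tp_rate``, or ``None``
    if no cutoff qualifies.  Cutoffs reporting zero precursors are
    skipped.
    """
    if table.empty:
        raise ValueError("score table is empty")
    if min_snr < 1:
        raise ValueError(f"min_snr must be >= 1, got {min_snr}")
    if not 0 <= min_tp_rate <= 1:
        raise ValueError(f"min_tp_rate must be in [0,1], got {min_tp_rate}")
    df = table.sort_values("cutoff")
    for _, row in df.iterrows():
        n, fp = float(row["n_reported"]), float(row["fp_mean"])
        if n == 0:
            continue
        snr = n / max(fp, SNR_EPS)
        tp = (n - fp) / n
        if snr >= min_snr and tp >= min_tp_rate:
            return float(row["cutoff"])
    return None
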