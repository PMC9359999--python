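"""Transcript abundance: TPM, replicate averaging, ranking, heatmap matrices.

Counts and effective lengths are the input contract (read mapping and count
estimation happen upstream); TPM_i = 1e6 * (c_i/l_i) / sum_j (c_j/l_j) per
sample, replicate TPMs are averaged arithmetically per tissue, and per-tissue
top-N transcripts feed a log2(mean TPM + pseudocount) heatmap matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    pass


def compute_tpm(counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """Transcripts-per-million from raw counts and effective lengths.

    All-zero counts yield all-zero TPM; otherwise the result sums to 1e6.
    TPM is invariant under uniform scaling of the counts.
    """
    if set(counts.index) != set(lengths.index):
        raise ExpressionError("counts and lengths index sets differ")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ExpressionError(f"non-positive effective length for {bad!r}")
    if (counts < 0).any():
        bad = counts.index[counts < 0][0]
        raise ExpressionError(f"negative count for {bad!r}")
    rate = counts.astype(float) / lengths.astype(float)
    total = rate.sum()
    if total == 0:
        return rate
    return 1e6 * rate / total


@dataclass
class ExpressionMatrix:
    """Per-sample counts and effective lengths plus derived TPM.

    ``counts`` and ``lengths`` are transcript x sample frames sharing index
    and columns; ``samples`` is indexed by sample id with columns ``tissue``
    and ``replicate``.
    """

    counts: pd.DataFrame
    lengths: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.lengths.columns):
            raise ExpressionError("counts/lengths sample columns differ")
        if list(self.counts.index) != list(self.lengths.index):
            raise ExpressionError("counts/lengths transcript indexes differ")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ExpressionError(f"samples manifest missing ids {sorted(missing)}")
        for col in ("tissue", "replicate"):
            if col not in self.samples.columns:
                raise ExpressionError(f"samples manifest lacks column {col!r}")

    @property
    def tpm(self) -> pd.DataFrame:
        """Per-sample TPM (each non-degenerate column sums to 1e6)."""
        return pd.DataFrame(
            {s: compute_tpm(self.counts[s], self.lengths[s]) for s in self.counts.columns}
        )

    def mean_tpm(self) -> pd.DataFrame:
        return average_replicates(self)


def average_replicates(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean TPM per transcript per tissue."""
    tpm = matrix.tpm
    tissues = matrix.samples.loc[list(tpm.columns), "tissue"]
    out = {}
    for tissue in sorted(tissues.unique()):
        cols = tissues.index[tissues == tissue]
        if len(cols) == 0:
            raise ExpressionError(f"tissue {tissue!r} has no replicates")
        out[tissue] = tpm[list(cols)].mean(axis=1)
    return pd.DataFrame(out)


def top_abundant(mean_tpm: pd.DataFrame, n: int, tissue: str) -> list[str]:
    """The n highest-mean-TPM transcripts in one tissue, descending.

    Ties are broken lexicographically by transcript id. Asking for more
    transcripts than exist returns all of them with a warning.
    """
    if n < 1:
        raise ExpressionError("n must be >= 1")
    if tissue not in mean_tpm.columns:
        raise ExpressionError(f"unknown tissue {tissue!r}")
    if n > len(mean_tpm):
        warnings.warn(
            f"requested top {n} but only {len(mean_tpm)} transcripts exist",
            stacklevel=2,
        )
        n = len(mean_tpm)
    series = mean_tpm[tissue]
    order = sorted(series.index, key=lambda t: (-series[t], t))
    return order[:n]


def heatmap_matrix(
    transcripts: list[str], mean_tpm: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(mean TPM + pseudocount) matrix, rows=transcripts, cols=tissues."""
    if pseudocount <= 0:
        raise ExpressionError("pseudocount must be > 0")
    missing = [t for t in transcripts if t not in mean_tpm.index]
    if missing:
        raise ExpressionError(f"transcripts not in table: {missing[:5]}")
    sub = mean_tpm.loc[list(transcripts)]
    return np.log2(sub + pseudocount)


# ---------------------------------------------------------------------------
# I/O


def load_expression(
    samples_manifest: str | Path, counts_dir: str | Path | None = None
) -> ExpressionMatrix:
    """Load per-sample count TSVs listed in a samples manifest.

    Manifest columns: sample_id, tissue, replicate, and optionally path
    (default ``<counts_dir>/<sample_id>.tsv``). Each count table has columns
    transcript_id, count, effective_length; a missing effective_length column
    falls back to sequence length if a ``length`` column exists.
    """
    manifest = pd.read_csv(samples_manifest, sep="\t")
    for col in ("sample_id", "tissue", "replicate"):
        if col not in manifest.columns:
            raise ExpressionError(f"samples manifest lacks column {col!r}")
    base = Path(counts_dir) if counts_dir else Path(samples_manifest).parent
    counts = {}
    lengths = {}
    for row in manifest.itertuples():
        raw = getattr(row, "path", None)
        if raw:
            path = Path(raw)
            if not path.is_absolute():
                path = base / path
        else:
            path = base / f"{row.sample_id}.tsv"
        table = pd.read_csv(path, sep="\t")
        if "effective_length" not in table.columns:
            if "length" in table.columns:
                logger.warning(
                    "%s: no effective_length column, falling back to length",
                    path,
                )
                table = table.rename(columns={"length": "effective_length"})
            else:
                raise ExpressionError(f"{path}: no effective_length column")
        table = table.set_index("transcript_id")
        counts[row.sample_id] = table["count"]
        lengths[row.sample_id] = table["effective_length"]
    counts_df = pd.DataFrame(counts)
    lengths_df = pd.DataFrame(lengths)
    if counts_df.isna().any().any() or lengths_df.isna().any().any():
        raise ExpressionError("sample tables disagree on transcript ids")
    return ExpressionMatrix(
        counts=counts_df,
        lengths=lengths_df,
        samples=manifest.set_index("sample_id"),
    )
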