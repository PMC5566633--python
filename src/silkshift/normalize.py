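"""Count normalization: TMM factors, CPM, FPKM, filtering, tissue means.

FPKM here is fragments per kilobase of *effective* transcript length per
million aligned fragments.  The TMM factor is applied to FPKM
multiplicatively by default (``tmm_apply="multiply"``); the more common
divide convention is available via the flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "tmm_factors",
    "compute_cpm",
    "low_expression_filter",
    "compute_fpkm",
    "mean_tissue_fpkm",
]

SAMPLE_SHEET_COLUMNS = ["species", "tissue", "replicate"]


@dataclass
class CountMatrix:
    """Transcript x library integer counts with lengths and library metadata.

    ``counts``: DataFrame, rows = transcripts, columns = libraries.
    ``effective_length``: Series, transcript -> effective length (bp) > 0.
    ``sample_sheet``: DataFrame indexed by library with columns
    (species, tissue, replicate).
    ``library_size``: Series library -> aligned fragments; defaults to the
    column sums of ``counts``.
    """

    counts: pd.DataFrame
    effective_length: pd.Series
    sample_sheet: pd.DataFrame
    library_size: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        self.validate()

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.sample_sheet.index)
        if missing:
            raise ValueError(f"libraries missing from sample sheet: {sorted(missing)}")
        lens = self.effective_length.reindex(self.counts.index)
        if lens.isna().any():
            bad = list(self.counts.index[lens.isna()])[:5]
            raise ValueError(f"transcripts without effective length: {bad}")
        if (lens <= 0).any():
            raise ValueError("effective lengths must be > 0")
        sizes = self.library_size.reindex(self.counts.columns)
        if (sizes <= 0).any():
            bad = list(sizes.index[sizes <= 0])
            raise ValueError(f"non-positive library sizes (all-zero counts?): {bad}")

    @property
    def libraries(self) -> pd.Index:
        return self.counts.columns

    def libraries_for(self, tissue: str | None = None, species: str | None = None) -> list[str]:
        sheet = self.sample_sheet.loc[list(self.counts.columns)]
        mask = pd.Series(True, index=sheet.index)
        if tissue is not None:
            mask &= sheet["tissue"] == tissue
        if species is not None:
            mask &= sheet["species"] == species
        return list(sheet.index[mask])

    def subset_libraries(self, libraries: list[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[libraries],
            effective_length=self.effective_length,
            sample_sheet=self.sample_sheet.loc[libraries],
            library_size=self.library_size[libraries],
        )


def _pick_reference(counts: pd.DataFrame, library_size: pd.Series) -> str:
    """Library whose upper-quartile CPM is closest to the mean upper-quartile."""
    rates = counts.div(library_size, axis=1)
    uq = rates.apply(lambda col: np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0)
    return str((uq - uq.mean()).abs().idxmin())


def _tmm_pair(
    y: np.ndarray,
    yr: np.ndarray,
    n: float,
    nr: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**)."""
    keep = (y > 0) & (yr > 0)
    y, yr = y[keep].astype(float), yr[keep].astype(float)
    if y.size == 0:
        return 1.0
    m = np.log2((y / n) / (yr / nr))
    a = 0.5 * np.log2((y / n) * (yr / nr))
    # inverse asymptotic variance of M (delta method, binomial sampling)
    w = (n - y) / (n * y) + (nr - yr) / (nr * yr)

    nk = m.size
    lo_m = np.floor(nk * logratio_trim) + 1
    hi_m = nk + 1 - lo_m
    lo_a = np.floor(nk * abs_trim) + 1
    hi_a = nk + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 1.0
    log2f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(log2f):
        return 1.0
    return float(2.0**log2f)


def tmm_factors(
    cm: CountMatrix,
    ref_library: str | None = None,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per library.

    Transcripts with a zero count in either library of a pair are excluded;
    M-values are weighted by inverse asymptotic variance and double-trimmed
    (default 30% on M, 5% on A).  Factors are rescaled so their geometric
    mean is 1.
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 libraries")
    zero_libs = [lib for lib in counts.columns if (counts[lib] == 0).all()]
    if zero_libs:
        raise ValueError(f"libraries with all-zero counts: {zero_libs}")
    lib_size = cm.library_size.reindex(counts.columns).astype(float)
    if ref_library is None:
        ref_library = _pick_reference(counts, lib_size)
    elif ref_library not in counts.columns:
        raise KeyError(f"unknown reference library {ref_library!r}")

    yr = counts[ref_library].to_numpy()
    nr = float(lib_size[ref_library])
    factors = {}
    for lib in counts.columns:
        if lib == ref_library:
            factors[lib] = 1.0
        else:
            factors[lib] = _tmm_pair(
                counts[lib].to_numpy(), yr, float(lib_size[lib]), nr, logratio_trim, abs_trim
            )
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def compute_cpm(cm: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Counts per million of TMM-effective library size."""
    if (factors.reindex(cm.libraries) <= 0).any():
        raise ValueError("TMM factors must be positive")
    eff = cm.library_size.reindex(cm.libraries) * factors.reindex(cm.libraries)
    return cm.counts.div(eff, axis=1) * 1e6


def low_expression_filter(cpm: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Transcripts with CPM >= threshold in at least one library."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if cpm.empty:
        return cpm.index[:0]
    return cpm.index[(cpm >= threshold).any(axis=1)]


def compute_fpkm(
    cm: CountMatrix, factors: pd.Series, tmm_apply: str = "multiply"
) -> pd.DataFrame:
    """TMM-normalized FPKM.

    Base FPKM = count / (effective_length/1e3 * library_size/1e6); the TMM
    factor is applied per library, multiplicatively by default.
    """
    if tmm_apply not in ("multiply", "divide"):
        raise ValueError("tmm_apply must be 'multiply' or 'divide'")
    lens = cm.effective_length.reindex(cm.counts.index)
    base = cm.counts.div(lens / 1e3, axis=0).div(
        cm.library_size.reindex(cm.libraries) / 1e6, axis=1
    )
    f = factors.reindex(cm.libraries)
    return base.mul(f, axis=1) if tmm_apply == "multiply" else base.div(f, axis=1)


def mean_tissue_fpkm(fpkm: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Mean FPKM per (species, tissue), averaged over replicate libraries.

    Returns a DataFrame with MultiIndex columns (species, tissue).
    """
    sheet = sample_sheet.reindex(fpkm.columns)
    if sheet[["species", "tissue"]].isna().any().any():
        bad = list(fpkm.columns[sheet["tissue"].isna()])
        raise ValueError(f"libraries without tissue mapping: {bad}")
    grouped = fpkm.T.groupby(
        [sheet["species"].to_numpy(), sheet["tissue"].to_numpy()]
    ).mean()
    out = grouped.T
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["species", "tissue"])
    return out


def species_profile(tissue_fpkm: pd.DataFrame, species: str) -> pd.DataFrame:
    """Single-species transcript x tissue slice of a mean-FPKM table."""
    if species not in tissue_fpkm.columns.get_level_values("species"):
        raise KeyError(f"unknown species {species!r}")
    return tissue_fpkm[species]
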